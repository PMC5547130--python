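"""iTRAQ 8-plex reporter-ion channel labels.

The eightplex reagent reports at nominal masses 113-119 and 121 (120 is
skipped by the chemistry to avoid the phenylalanine immonium ion).  Channel
labels are carried as strings throughout; the peptide-table column for a
channel is ``ch<label>``.
"""

from __future__ import annotations

ITRAQ8: tuple[str, ...] = ("113", "114", "115", "116", "117", "118", "119", "121")

#: Marker used in design channel maps for the pooled global internal standard.
GIS_MARKER = "GIS"


def intensity_column(channel: str) -> str:
    """Column name holding reporter-ion intensities for *channel*."""
    return f"ch{channel}"


INTENSITY_COLUMNS: tuple[str, ...] = tuple(intensity_column(c) for c in ITRAQ8)
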