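"""Destrieux-style parcellation label table.

The analysis targets 191 brain areas: the 74 Destrieux cortical regions
per hemisphere plus 43 subcortical segmentation structures.  The table
shipped here gives integer label codes, region names, hemisphere, and
group; it defines the ROI vocabulary when real parcellations are
consumed (the synthetic phantoms use plain 1..K labels instead).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_destrieux_table() -> pd.DataFrame:
    """The 191-entry parcellation label table (label, name, hemisphere, group)."""
    with resources.files("radiomath.data").joinpath("destrieux_labels.csv").open() as fh:
        return pd.read_csv(fh)
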