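"""Bundled example data.

The example trait table summarises a published 16-generation selective
breeding experiment for home-cage hyperactivity in mice (a High-Active line
against a randomly bred Control line): per-line means, SEMs and group sizes
for home-cage activity, Go/No-go endpoints, Y-maze and rotarod traits, with
literature heritabilities and family counts where available.  The colony's
pedigree inbreeding coefficient was F = 0.06217.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .summaries import TraitRecord, read_trait_table

__all__ = ["load_highactive_example", "load_highactive_frame", "HIGHACTIVE_F"]

#: pedigree inbreeding coefficient of the example colony
HIGHACTIVE_F = 0.06217

_DATA = "highactive_line_summaries.csv"


def _path():
    return resources.files("linedrift.data").joinpath(_DATA)


def load_highactive_frame() -> pd.DataFrame:
    """The example trait table as a raw DataFrame."""
    with resources.as_file(_path()) as p:
        return pd.read_csv(p)


def load_highactive_example() -> list[TraitRecord]:
    """The example trait table as TraitRecords."""
    with resources.as_file(_path()) as p:
        return read_trait_table(p)
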