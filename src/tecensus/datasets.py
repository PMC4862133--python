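"""Bundled reference tables.

Two small published tables ship with the package as plain TSV:

* the per-superfamily TE mass census of the two *D. buzzatii* strains
  (st-1, j-19; annotated and coverage-corrected kb) and *D. mojavensis*;
* the TE percentage survey of 27 *Drosophila* genome assemblies with their
  sequencing technology (Sanger vs NGS).

They serve as worked-example inputs for the correction-factor and
group-comparison operations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("tecensus.data") / name) as p:
        return pd.read_csv(p, sep="\t")


def load_buzzatii_te_mass() -> pd.DataFrame:
    """Superfamily-level TE mass (kb) for D. buzzatii st-1/j-19 and D. mojavensis.

    Columns: order, superfamily, st1_kb, st1_corrected_kb, j19_kb,
    j19_corrected_kb, mojavensis_kb.
    """
    return _load("buzzatii_te_mass.tsv")


def load_drosophila_te_survey() -> pd.DataFrame:
    """TE percentages of 27 Drosophila assemblies with sequencing-method labels."""
    df = _load("drosophila_te_survey.tsv")
    return df.fillna({"strain": ""})
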