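"""Bundled reference result tables for validation and reporting tests.

The package ships, as plain TSV, the published per-method MR result tables of
a two-sample study of gut-microbiota abundances (MiBioGen consortium
exposures) against five geriatric-syndrome outcomes: frailty, Parkinson's
disease, delirium, insomnia and depression.  Each row is one (taxon, method)
estimate: taxonomic rank, taxon label, number of instruments, method, SE of
the log-OR, OR with 95% CI, and p-value, transcribed as printed (including a
handful of typographical oddities in the source tables, which are noted in
the methods documentation and excluded from any numeric check).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

#: Outcome keys of the bundled tables, in publication order.
OUTCOMES = ("frailty", "pd", "delirium", "insomnia", "depression")


def load_reference_table(outcome: str) -> pd.DataFrame:
    """Load one bundled per-outcome result table as a DataFrame."""
    if outcome not in OUTCOMES:
        raise KeyError(f"unknown outcome {outcome!r}; expected one of {OUTCOMES}")
    ref = resources.files("tsmr.data").joinpath(f"{outcome}.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_all_reference_tables() -> dict[str, pd.DataFrame]:
    return {o: load_reference_table(o) for o in OUTCOMES}


__all__ = ["OUTCOMES", "load_reference_table", "load_all_reference_tables"]
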