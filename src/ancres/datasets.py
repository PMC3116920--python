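"""Packaged reference tables.

Small published measurements ship with the package as plain-text data so
the downstream arithmetic (fold changes, stability regressions) can be
exercised without external files: the DOC dose-response summary for the
ancestral corticoid receptor, its mutants and the resurrected ancestral
GR (fitted logEC50 +/- SE), and the predicted stability effects (mean
ddG over five energy-function runs) for the large-effect and buffering
mutants. Both are inputs to this package, produced upstream by wet-lab
assays and an external energy function respectively.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _data_path(name: str):
    return resources.files("ancres") / "data" / name


def doc_sensitivity_table() -> pd.DataFrame:
    """Fitted logEC50 +/- SE for DOC across receptors (published summary)."""
    with resources.as_file(_data_path("doc_sensitivity.csv")) as p:
        return pd.read_csv(p)


def ddg_means() -> dict[str, float]:
    """Published mean ddG (kcal/mol) per mutant, averaged over five runs."""
    with resources.as_file(_data_path("ddg_means.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    return dict(zip(df["mutant"], df["ddG_kcal_mol"]))
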