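"""emPAI quantification and molar-percentage normalisation.

emPAI = 10^(N_observed / N_observable) - 1, where N_observed is the
number of distinct identified peptide sequences of a protein in a run
and N_observable the number of distinct observable tryptic peptides of
its sequence. Molar percentages normalise each protein's emPAI by the
sum of all emPAI values within the same (sample, fraction, replicate)
run, so every run's percentages sum to 100.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .digestion import ObservabilityWindow, count_observable
from .pipeline import ProteinIdentification

QUANT_COLUMNS = [
    "orf_id", "sample", "fraction", "replicate",
    "n_observed", "n_observable", "pai", "empai", "molar_pct",
]


class QuantError(ValueError):
    pass


def empai(n_observed: int, n_observable: int) -> float:
    """10^(N_obsd/N_obsbl) - 1."""
    if n_observable < 1:
        raise QuantError("protein has no observable peptides")
    if n_observed < 0:
        raise QuantError("negative observed count")
    return 10.0 ** (n_observed / n_observable) - 1.0


def molar_percentages(df: pd.DataFrame) -> pd.DataFrame:
    """Fill molar_pct per (sample, fraction, replicate) run; each run's
    column sums to 100."""
    df = df.copy()
    run = ["sample", "fraction", "replicate"]
    totals = df.groupby(run)["empai"].transform("sum")
    if (totals <= 0).any():
        raise QuantError("run with all-zero emPAI cannot be normalised")
    df["molar_pct"] = 100.0 * df["empai"] / totals
    return df


def quantify(
    identifications: Iterable[ProteinIdentification],
    orf_seqs: Mapping[str, str],
    window: ObservabilityWindow = ObservabilityWindow(),
    max_missed: int = 1,
) -> pd.DataFrame:
    """One quant row per (orf_id, sample, fraction, replicate).

    Proteins with no observable peptide are excluded with a warning —
    emPAI is undefined for them.
    """
    observable_cache: dict[str, int] = {}
    rows = []
    for ident in identifications:
        if ident.orf_id not in observable_cache:
            observable_cache[ident.orf_id] = count_observable(
                orf_seqs[ident.orf_id], window=window, max_missed=max_missed
            )
        n_obs = observable_cache[ident.orf_id]
        if n_obs < 1:
            import warnings

            warnings.warn(f"{ident.orf_id}: no observable peptides, excluded")
            continue
        pai = ident.n_observed / n_obs
        rows.append(
            {
                "orf_id": ident.orf_id,
                "sample": ident.sample,
                "fraction": ident.fraction,
                "replicate": ident.replicate,
                "n_observed": ident.n_observed,
                "n_observable": n_obs,
                "pai": pai,
                "empai": 10.0**pai - 1.0,
            }
        )
    if not rows:
        return pd.DataFrame(columns=QUANT_COLUMNS)
    df = pd.DataFrame(rows).sort_values(
        ["sample", "fraction", "replicate", "orf_id"], ignore_index=True
    )
    return molar_percentages(df)


def aggregate_class_abundance(
    df: pd.DataFrame, class_map: Mapping[str, str]
) -> pd.DataFrame:
    """Per-run molar_pct sums by protein class label.

    Proteins absent from ``class_map`` fall into 'unassigned'; per-run
    label sums total 100.
    """
    df = df.copy()
    df["label"] = df["orf_id"].map(lambda o: class_map.get(o, "unassigned"))
    out = (
        df.groupby(["sample", "fraction", "replicate", "label"], as_index=False)[
            "molar_pct"
        ]
        .sum()
        .rename(columns={"molar_pct": "molar_pct_sum"})
    )
    return out


def abundance_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Proteins x runs molar_pct matrix (missing cells 0); run columns are
    '<sample>:<fraction>:<replicate>' labels."""
    df = df.copy()
    df["run"] = (
        df["sample"].astype(str)
        + ":" + df["fraction"].astype(str)
        + ":" + df["replicate"].astype(str)
    )
    mat = df.pivot_table(
        index="orf_id", columns="run", values="molar_pct", fill_value=0.0,
        aggfunc="sum",
    )
    mat = mat.sort_index(axis=0).sort_index(axis=1)
    mat.columns.name = None
    mat.index.name = "orf_id"
    return mat
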