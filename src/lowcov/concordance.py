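"""Genotype and allele concordance between called and true genotypes.

Genotype concordance is the percentage of called genotypes that match the
truth.  Allele concordance is the percentage of matched alleles: an
unphased diploid genotype pair with dosage difference ``|Δd|`` shares
``2 - |Δd|`` of its two alleles, so a hom-het mismatch still matches one
allele.  Pairs where either side is missing or no-call are excluded from
every denominator, and the called-vs-true confusion matrix is expressed as
column percentages: entry (called x | true y) is the percent of
called-x among true-y pairs.  Tables can be stratified by site coverage.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import NO_CALL

DOSAGES = (0, 1, 2)


@dataclass
class ConcordanceTable:
    """Concordance summary; ``confusion[called, true]`` are column percents."""

    n_called: int
    genotype_concordance: float
    allele_concordance: float
    confusion: np.ndarray  # 3x3 percent, columns = true genotype
    counts: np.ndarray  # 3x3 raw pair counts
    strata: dict[str, "ConcordanceTable"] = field(default_factory=dict)

    def percent(self, called: int, true: int) -> float:
        """Confusion entry ``called|true`` as a percentage (NaN if no pairs)."""
        return float(self.confusion[called, true])

    def variables(self) -> dict[str, float]:
        """The nine confusion percentages keyed ``"called|true"``."""
        return {
            f"{c}|{t}": float(self.confusion[c, t]) for t in DOSAGES for c in DOSAGES
        }

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (stratum, true, called) cell."""
        rows = []

        def emit(label: str, tab: "ConcordanceTable") -> None:
            for t in DOSAGES:
                for c in DOSAGES:
                    rows.append(
                        (label, t, c, int(tab.counts[c, t]), float(tab.confusion[c, t]))
                    )

        emit("overall", self)
        for label, tab in self.strata.items():
            emit(label, tab)
        return pd.DataFrame(rows, columns=["stratum", "true", "called", "n", "percent"])


def _one_table(true: np.ndarray, called: np.ndarray) -> ConcordanceTable:
    n = true.size
    counts = np.zeros((3, 3), dtype=np.int64)
    if n:
        np.add.at(counts, (called, true), 1)
    col = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        confusion = 100.0 * counts / col
    geno = 100.0 * np.trace(counts) / n if n else float("nan")
    allele = (
        100.0 * np.mean((2 - np.abs(true - called)) / 2.0) if n else float("nan")
    )
    return ConcordanceTable(n, geno, allele, confusion, counts)


def build_concordance(
    true_calls, test_calls, strata=None
) -> ConcordanceTable:
    """Concordance of ``test_calls`` against ``true_calls``.

    Both inputs are dosage arrays (any shape, element-wise paired); values
    outside {0, 1, 2} - including :data:`~lowcov.types.NO_CALL` and NaN -
    mark a missing side and the pair is excluded everywhere.  ``strata``,
    if given, is an array of stratum labels aligned with the inputs; pairs
    labelled ``"excluded"`` appear in the overall table only if their label
    says otherwise, per-stratum tables are computed on each label's subset.
    """
    true = _as_dosage(true_calls)
    called = _as_dosage(test_calls)
    if true.shape != called.shape:
        raise ValueError(
            f"true and called tables have different shapes: {true.shape} vs {called.shape}"
        )
    valid = _is_called(true) & _is_called(called)
    table = _one_table(true[valid], called[valid])
    if strata is not None:
        strata = np.asarray(strata)
        if strata.shape != true.shape:
            raise ValueError("strata labels must align with the dosage tables")
        for label in pd.unique(strata.ravel()):
            mask = valid & (strata == label)
            table.strata[str(label)] = _one_table(true[mask], called[mask])
    return table


def _as_dosage(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    arr = np.where(np.isnan(arr), NO_CALL, arr)
    return arr.astype(np.int64)


def _is_called(d: np.ndarray) -> np.ndarray:
    return (d >= 0) & (d <= 2)


# ---------------------------------------------------------------------------
# Table-level pipeline (truth TSV + calls TSV [+ counts TSV] -> tables)


def concordance_from_tables(
    truth: pd.DataFrame,
    calls: pd.DataFrame,
    counts: pd.DataFrame | None = None,
    bins=None,
) -> ConcordanceTable:
    """Join truth and call tables on (sample, contig, pos) and summarise.

    ``truth`` needs columns ``sample, contig, pos, dosage``; ``calls`` the
    same (the genotyper's output format).  If ``counts`` is given the
    result is additionally stratified by site coverage using ``bins``
    (default strata 1x..5x and 6-10x).
    """
    from .readcounts import DEFAULT_BINS

    keys = ["sample", "contig", "pos"]
    merged = truth[keys + ["dosage"]].rename(columns={"dosage": "true"}).merge(
        calls[keys + ["dosage"]].rename(columns={"dosage": "called"}),
        on=keys,
        how="inner",
        validate="one_to_one",
    )
    if merged.empty:
        raise ValueError("truth and calls tables share no (sample, contig, pos) keys")
    strata = None
    if counts is not None:
        bins = bins or DEFAULT_BINS
        merged = merged.merge(counts[keys + ["nRef", "nAlt"]], on=keys, how="left")
        depth = (merged["nRef"].fillna(0) + merged["nAlt"].fillna(0)).to_numpy()
        strata = bins.labels(depth)
    true = merged["true"].astype("Int64").fillna(NO_CALL).to_numpy(dtype=np.int64)
    called = merged["called"].astype("Int64").fillna(NO_CALL).to_numpy(dtype=np.int64)
    return build_concordance(true, called, strata)


def summary_frame(table: ConcordanceTable) -> pd.DataFrame:
    """Wide per-stratum summary: n, concordances and the nine confusion cells."""
    rows = []

    def emit(label: str, tab: ConcordanceTable) -> None:
        row = {
            "stratum": label,
            "n": tab.n_called,
            "genotype_concordance": round(tab.genotype_concordance, 2),
            "allele_concordance": round(tab.allele_concordance, 2),
        }
        for name, value in tab.variables().items():
            row[name] = round(value, 2) if np.isfinite(value) else np.nan
        rows.append(row)

    for label, tab in table.strata.items():
        emit(label, tab)
    emit("overall", table)
    return pd.DataFrame(rows)


def write_concordance(table: ConcordanceTable, out_dir: str | os.PathLike) -> dict:
    """Write long-format and summary TSVs; returns the paths written."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    long_path = out / "concordance_long.tsv"
    table.to_frame().to_csv(long_path, sep="\t", index=False, float_format="%.2f")
    summary_path = out / "concordance_summary.tsv"
    summary_frame(table).to_csv(summary_path, sep="\t", index=False)
    return {"long": str(long_path), "summary": str(summary_path)}
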