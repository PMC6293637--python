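"""Genotype probabilities, calling modes and the pruning-bias emulator.

Given allele read counts (nRef, nAlt) at a biallelic site and a sequencing
error rate *e*, the three genotype likelihoods are

    p(0) = (1 - e)^nRef * e^nAlt          (reference homozygote)
    p(1) = 0.5^nRef * 0.5^nAlt            (heterozygote)
    p(2) = e^nRef * (1 - e)^nAlt          (alternative homozygote)

scaled to sum to one.  Calls are made in four modes: best-guess (the most
probable genotype), two thresholded modes requiring the top probability to
exceed 0.90 or 0.98, and presence/absence calling in which a single read of
each allele suffices to declare that allele present (the zero-error limit
of best-guess calling).

:func:`emulate_pruning` reproduces, at the level of allele counts, the bias
mechanism of local-assembly variant callers that prune graph paths with
fewer supporting reads than a threshold: weakly supported alternative
alleles are re-attributed to the reference, which at low coverage turns
true heterozygotes and even alternative homozygotes into apparent
reference homozygotes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .types import NO_CALL

DEFAULT_ERROR_RATE = 0.01

MODES = ("best-guess", "p>0.90", "p>0.98", "presence/absence")

_MODE_ALIASES = {
    "best-guess": "best-guess", "best_guess": "best-guess", "bestguess": "best-guess",
    "p>0.90": "p>0.90", "p90": "p>0.90", "0.90": "p>0.90",
    "p>0.98": "p>0.98", "p98": "p>0.98", "0.98": "p>0.98",
    "presence/absence": "presence/absence", "presence": "presence/absence",
    "pa": "presence/absence",
}

_THRESHOLDS = {"p>0.90": 0.90, "p>0.98": 0.98}


def canonical_mode(mode: str) -> str:
    try:
        return _MODE_ALIASES[mode.lower()]
    except KeyError:
        raise ValueError(f"unknown calling mode {mode!r}; expected one of {MODES}") from None


def _check_error_rate(e: float) -> None:
    if not 0.0 < e < 0.5:
        raise ValueError(f"sequencing error rate must be in (0, 0.5), got {e}")


def genotype_probabilities(nref, nalt, e: float = DEFAULT_ERROR_RATE) -> np.ndarray:
    """Scaled genotype probabilities (p0, p1, p2) from allele read counts.

    Accepts scalars or arrays (broadcast together); returns an array whose
    last axis holds (p0, p1, p2).  Computed in log space so that deep sites
    do not underflow.  At depth 0 all three probabilities are 1/3.
    """
    _check_error_rate(e)
    nref = np.asarray(nref, dtype=np.float64)
    nalt = np.asarray(nalt, dtype=np.float64)
    if (nref < 0).any() or (nalt < 0).any():
        raise ValueError("allele counts must be non-negative")
    log_e, log_1e, log_h = np.log(e), np.log1p(-e), np.log(0.5)
    logs = np.stack(
        [
            nref * log_1e + nalt * log_e,
            (nref + nalt) * log_h,
            nref * log_e + nalt * log_1e,
        ],
        axis=-1,
    )
    logs -= logs.max(axis=-1, keepdims=True)
    probs = np.exp(logs)
    probs /= probs.sum(axis=-1, keepdims=True)
    return probs


def call_genotypes(nref, nalt, mode: str = "best-guess",
                   e: float = DEFAULT_ERROR_RATE) -> np.ndarray:
    """Vectorised genotype calls; returns dosages with ``-1`` for no-call.

    Best-guess returns the most probable genotype, with no-call at depth 0
    or on an exact tie of the maxima.  The thresholded modes call only when
    the top probability *strictly* exceeds the threshold.  Presence/absence
    ignores ``e``: heterozygote if both alleles have support, the matching
    homozygote if only one does, no-call at depth 0.
    """
    mode = canonical_mode(mode)
    nref, nalt = np.broadcast_arrays(np.asarray(nref), np.asarray(nalt))
    scalar = nref.ndim == 0
    nref, nalt = np.atleast_1d(nref), np.atleast_1d(nalt)
    depth = nref + nalt

    if mode == "presence/absence":
        out = np.full(nref.shape, NO_CALL, dtype=np.int8)
        out[(nref > 0) & (nalt == 0)] = 0
        out[(nref > 0) & (nalt > 0)] = 1
        out[(nref == 0) & (nalt > 0)] = 2
        return out[0] if scalar else out

    probs = genotype_probabilities(nref, nalt, e)
    best = probs.argmax(axis=-1).astype(np.int8)
    top = np.take_along_axis(probs, best[..., None].astype(np.intp), axis=-1)[..., 0]
    tied = (np.isclose(probs, top[..., None], rtol=0, atol=0).sum(axis=-1)) > 1

    out = best.copy()
    out[depth == 0] = NO_CALL
    out[tied] = NO_CALL
    if mode in _THRESHOLDS:
        out[top <= _THRESHOLDS[mode]] = NO_CALL
    return out[0] if scalar else out


@dataclass(frozen=True)
class GenotypeCall:
    """A single call with its scaled probabilities and the mode that made it."""

    dosage: int  # 0, 1, 2 or NO_CALL
    p0: float
    p1: float
    p2: float
    mode: str


def call_genotype(nref: int, nalt: int, mode: str = "best-guess",
                  e: float = DEFAULT_ERROR_RATE) -> GenotypeCall:
    """Scalar convenience wrapper around :func:`call_genotypes`."""
    mode = canonical_mode(mode)
    dosage = int(call_genotypes(np.array(nref), np.array(nalt), mode, e))
    if mode == "presence/absence":
        p0 = p1 = p2 = float("nan")
    else:
        p0, p1, p2 = genotype_probabilities(nref, nalt, e)
    return GenotypeCall(dosage, float(p0), float(p1), float(p2), mode)


def emulate_pruning(nref, nalt, min_pruning: int = 2):
    """Emulate the variant caller's pruning bias on allele counts.

    Local re-assembly prunes graph paths supported by fewer reads than
    ``min_pruning``; reads from a pruned alternative path are then forced
    onto the only haplotype left - the reference - so their support is
    re-attributed to the reference allele.  The reference path itself is
    always present in the graph and is never pruned, which is exactly why
    the bias is one-sided.

    Returns ``(nRef + nAlt, 0)`` when ``nAlt < min_pruning``, the counts
    unchanged otherwise.  Total depth is always preserved.  Accepts scalars
    or arrays.
    """
    if min_pruning < 1:
        raise ValueError("min_pruning must be >= 1")
    nref = np.asarray(nref)
    nalt = np.asarray(nalt)
    pruned = nalt < min_pruning
    new_ref = np.where(pruned, nref + nalt, nref)
    new_alt = np.where(pruned, 0, nalt)
    if new_ref.ndim == 0:
        return int(new_ref), int(new_alt)
    return new_ref, new_alt


# ---------------------------------------------------------------------------
# Table-level pipeline (counts TSV -> calls TSV)


def call_table(counts: pd.DataFrame, mode: str = "best-guess",
               e: float = DEFAULT_ERROR_RATE,
               emulate_pruning_threshold: int | None = None) -> pd.DataFrame:
    """Call genotypes for a counts table (readcounts TSV dialect).

    Returns a table with columns ``sample, contig, pos, dosage, p0, p1,
    p2, mode``; ``dosage`` is nullable (pandas NA for no-call).
    """
    mode = canonical_mode(mode)
    nref = counts["nRef"].to_numpy()
    nalt = counts["nAlt"].to_numpy()
    if emulate_pruning_threshold is not None:
        nref, nalt = emulate_pruning(nref, nalt, emulate_pruning_threshold)
    dosage = call_genotypes(nref, nalt, mode, e)
    out = counts.loc[:, [c for c in ("sample", "contig", "pos") if c in counts.columns]].copy()
    out["dosage"] = pd.array(dosage, dtype="Int64")
    out.loc[out["dosage"] == NO_CALL, "dosage"] = pd.NA
    if mode == "presence/absence":
        out["p0"] = out["p1"] = out["p2"] = np.nan
    else:
        probs = genotype_probabilities(nref, nalt, e)
        out["p0"], out["p1"], out["p2"] = probs[..., 0], probs[..., 1], probs[..., 2]
    out["mode"] = mode
    return out


def write_calls_tsv(calls: pd.DataFrame, path: str | os.PathLike) -> None:
    calls.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


def read_calls_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values="NA")
    df["dosage"] = df["dosage"].astype("Int64")
    return df
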