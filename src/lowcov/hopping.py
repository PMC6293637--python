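"""Index-hopping simulation and estimation.

Index hopping misassigns reads between multiplexed samples sharing a flow
cell.  Its incidence in a low-coverage multiplexed dataset can be measured
empirically when the same samples are also sequenced unmultiplexed at high
coverage: the high-coverage reads are down-sampled to the low-coverage
depth to give hop-free data, known hop levels are injected in silico, and
the genotype-concordance variables of the real multiplexed data are placed
on the calibration curve of the simulated levels by inverse regression.

Two response families are supported: raw concordance percentages (fitted
with degree-1 least squares) and isometric log-ratio (ilr) transforms of
the concordance composition (fitted with degree-2 least squares), the
latter because percentages are compositional - relative, not absolute -
information.  The ilr forms are

    3-part:  sqrt(2/3) * ln( c_correct / sqrt(c_err_a * c_err_b) )
    2-part:  (1/sqrt 2) * ln( c_correct / c_err )

which are scale-invariant, so raw counts and percentages give identical
values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concordance import build_concordance
from .genotyper import call_genotypes
from .simulate import tally_counts
from .types import MultiplexReadSet

#: Hop levels (percent) used for the calibration grid by default.
DEFAULT_LEVELS = (0.0, 0.1, 0.5, 1.0, 2.0, 5.0)

#: Confusion variables whose true genotype is homozygous; these respond
#: almost linearly to hopping while the heterozygote variables barely move
#: (a hopped read landing on a heterozygote usually supports one of the
#: two alleles already present).
HOMOZYGOTE_VARIABLES = ("0|0", "1|0", "2|0", "0|2", "1|2", "2|2")


# ---------------------------------------------------------------------------
# Read-set manipulation


def downsample(reads: MultiplexReadSet, fraction: float, seed: int = 0) -> MultiplexReadSet:
    """Keep each fragment independently with probability ``fraction``.

    Emulates the random sampling of reads that occurs during sequencing;
    calibration data sets are down-sampled independently of one another.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"fraction must be in [0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    keep = rng.random(len(reads)) < fraction
    return reads.subset(keep)


def inject_hopping(reads: MultiplexReadSet, h: float, seed: int = 0) -> MultiplexReadSet:
    """Reassign each fragment with probability ``h`` to another sample.

    The target is uniform over the other ``n - 1`` samples.  Fragments hop
    atomically (index hopping is a library-fragment phenomenon: both mates
    carry the same index pair), total fragment count is conserved, and the
    per-site read totals across the whole multiplex are unchanged - hopping
    moves reads between samples, it does not create or destroy them.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"hop probability must be in [0, 1], got {h}")
    n_samples = reads.n_samples
    if h > 0 and n_samples < 2:
        raise ValueError("cannot inject hopping into a single-sample multiplex")
    out = reads.copy()
    if h == 0 or len(reads) == 0:
        return out
    rng = np.random.default_rng(seed)
    hop = rng.random(len(reads)) < h
    n_hop = int(hop.sum())
    # uniform over the other samples: add a nonzero offset modulo n
    offset = rng.integers(1, n_samples, size=n_hop)
    out.assigned_sample[hop] = (
        (out.assigned_sample[hop].astype(np.int64) + offset) % n_samples
    ).astype(np.int32)
    return out


# ---------------------------------------------------------------------------
# Isometric log-ratios


def ilr_3part(c_correct: float, c_err_a: float, c_err_b: float) -> float:
    """3-part ilr: sqrt(2/3) * ln(c_correct / sqrt(c_err_a * c_err_b)).

    All parts must be strictly positive; a zero part makes the log-ratio
    undefined and raises rather than being silently perturbed.
    """
    if c_correct <= 0 or c_err_a <= 0 or c_err_b <= 0:
        raise ValueError(
            "ilr parts must be strictly positive, got "
            f"({c_correct}, {c_err_a}, {c_err_b})"
        )
    return math.sqrt(2.0 / 3.0) * math.log(c_correct / math.sqrt(c_err_a * c_err_b))


def ilr_2part(c_correct: float, c_err: float) -> float:
    """2-part ilr: (1/sqrt 2) * ln(c_correct / c_err); parts must be > 0."""
    if c_correct <= 0 or c_err <= 0:
        raise ValueError(f"ilr parts must be strictly positive, got ({c_correct}, {c_err})")
    return math.log(c_correct / c_err) / math.sqrt(2.0)


#: ilr variables derived from the nine confusion percentages.  The 3-part
#: ratios compare each true-genotype column's correct calls against both
#: error classes; the 2-part ratios compare correct homozygote calls
#: against the incorrect heterozygote calls.
ILR_VARIABLES = (
    "0|0 vs 1|0, 2|0",
    "1|1 vs 0|1, 2|1",
    "2|2 vs 0|2, 1|2",
    "0|0 vs 1|0",
    "2|2 vs 1|2",
)

#: ilr variables whose true genotype is homozygous.
HOMOZYGOTE_ILR_VARIABLES = (
    "0|0 vs 1|0, 2|0",
    "2|2 vs 0|2, 1|2",
    "0|0 vs 1|0",
    "2|2 vs 1|2",
)


def ilr_variables(percent: dict) -> dict:
    """Compute the standard ilr variables from confusion percentages.

    ``percent`` maps ``"called|true"`` to a percentage (the output of
    :meth:`ConcordanceTable.variables`).
    """
    p = percent
    return {
        "0|0 vs 1|0, 2|0": ilr_3part(p["0|0"], p["1|0"], p["2|0"]),
        "1|1 vs 0|1, 2|1": ilr_3part(p["1|1"], p["0|1"], p["2|1"]),
        "2|2 vs 0|2, 1|2": ilr_3part(p["2|2"], p["0|2"], p["1|2"]),
        "0|0 vs 1|0": ilr_2part(p["0|0"], p["1|0"]),
        "2|2 vs 1|2": ilr_2part(p["2|2"], p["1|2"]),
    }


# ---------------------------------------------------------------------------
# Regression and inverse prediction


@dataclass(frozen=True)
class RegressionFit:
    """A least-squares polynomial fit of a response on hop level (percent)."""

    degree: int
    coefficients: tuple  # ascending: intercept, slope(, curvature)
    r_squared: float
    levels: tuple
    responses: tuple

    def predict(self, level):
        level = np.asarray(level, dtype=float)
        return sum(c * level**k for k, c in enumerate(self.coefficients))


def fit_level_regression(levels, responses, degree: int = 1) -> RegressionFit:
    """Ordinary least squares of a response on hop level (and level² if 2).

    Requires at least ``degree + 2`` distinct levels so the fit is
    overdetermined and R² is meaningful.
    """
    levels = np.asarray(levels, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if degree not in (1, 2):
        raise ValueError("degree must be 1 or 2")
    if len(np.unique(levels)) != len(levels):
        raise ValueError("hop levels must be distinct")
    if len(levels) < degree + 2:
        raise ValueError(f"need at least {degree + 2} points for a degree-{degree} fit")
    design = np.vander(levels, degree + 1, increasing=True)
    coef, _, rank, _ = np.linalg.lstsq(design, responses, rcond=None)
    if rank < degree + 1:
        raise ValueError("rank-deficient design; check the level grid")
    fitted = design @ coef
    ss_res = float(((responses - fitted) ** 2).sum())
    ss_tot = float(((responses - responses.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return RegressionFit(degree, tuple(coef), r2, tuple(levels), tuple(responses))


def estimate_hop_level(fit: RegressionFit, observed: float) -> float:
    """Invert a calibration fit at an observed response; returns percent.

    Degree 1 solves the line directly.  Degree 2 takes the real root of
    the fitted quadratic that lies within the calibrated level span (the
    smaller such root if both qualify); the response curves are monotone
    over the span, so at most one interior root occurs in practice.
    """
    lo, hi = min(fit.levels), max(fit.levels)
    if fit.degree == 1:
        b0, b1 = fit.coefficients
        scale = max(1.0, abs(b0))
        if abs(b1) < 1e-12 * scale:
            raise ValueError("zero slope: response does not depend on hop level")
        return (observed - b0) / b1
    b0, b1, b2 = fit.coefficients
    roots = np.roots([b2, b1, b0 - observed])
    real = [float(r.real) for r in roots if abs(r.imag) < 1e-9]
    eps = 1e-9 * max(1.0, hi)
    in_range = sorted(r for r in real if lo - eps <= r <= hi + eps)
    if not in_range:
        raise ValueError(
            f"observed response {observed} is outside the calibrated range [{lo}, {hi}]"
        )
    return in_range[0]


# ---------------------------------------------------------------------------
# End-to-end calibration pipeline on simulated multiplexes


def concordance_variables(reads: MultiplexReadSet, truth, mode: str = "presence/absence",
                          e: float = 0.01) -> dict:
    """Call genotypes from a read set and return the confusion percentages.

    Counts are tallied per *assigned* sample, genotypes called in ``mode``,
    and the nine ``"called|true"`` percentages computed against the truth
    dosages.
    """
    nref, nalt = tally_counts(reads, truth.n_samples, truth.n_sites)
    called = call_genotypes(nref, nalt, mode=mode, e=e)
    return build_concordance(truth.genotypes, called).variables()


def calibration_table(
    base_reads: MultiplexReadSet,
    truth,
    levels=DEFAULT_LEVELS,
    fraction: float = 1.0 / 15.0,
    seed: int = 0,
    mode: str = "presence/absence",
    e: float = 0.01,
) -> pd.DataFrame:
    """Build the hop-level calibration grid from a high-coverage read set.

    For each level (percent) the base reads are down-sampled independently
    by ``fraction``, hopping is injected at that level, genotypes are
    called and the confusion percentages recorded.  Returns a long table
    with columns ``level_percent, variable, value``.
    """
    levels = sorted(float(l) for l in levels)
    if any(l < 0 or l > 100 for l in levels):
        raise ValueError("hop levels are percentages in [0, 100]")
    ss = np.random.SeedSequence(seed)
    rows = []
    for level, child in zip(levels, ss.spawn(len(levels))):
        s1, s2 = child.generate_state(2) >> np.uint32(1)  # keep below 2**31
        ds = downsample(base_reads, fraction, int(s1))
        hp = inject_hopping(ds, level / 100.0, int(s2))
        for var, value in concordance_variables(hp, truth, mode, e).items():
            rows.append((level, var, value))
    return pd.DataFrame(rows, columns=["level_percent", "variable", "value"])


def estimate_hopping(
    calibration: pd.DataFrame,
    observed: dict | pd.DataFrame,
    response: str = "percent",
    degree: int | None = None,
    variables=None,
) -> pd.DataFrame:
    """Per-variable inverse-regression hop estimates from a calibration grid.

    ``calibration`` is the long table of :func:`calibration_table` (or any
    table with columns ``level_percent, variable, value``); ``observed``
    maps variable name to the observed response.  ``response`` selects the
    fitted quantity: ``"percent"`` (raw concordance percentages, degree-1
    fit by default) or ``"ilr3"``/``"ilr2"``/``"ilr"`` (ilr transforms,
    degree-2 fit by default).  Returns one row per variable with the
    estimate (percent), R² and the degree used, plus the min/max range of
    the estimates in ``DataFrame.attrs["range"]``.
    """
    if isinstance(observed, pd.DataFrame):
        observed = dict(zip(observed["variable"], observed["value"]))
    wide = calibration.pivot(index="level_percent", columns="variable", values="value")
    levels = wide.index.to_numpy(dtype=float)

    if response == "percent":
        degree = 1 if degree is None else degree
        resp_wide = wide
        obs = dict(observed)
    elif response in ("ilr", "ilr3", "ilr2"):
        degree = 2 if degree is None else degree
        rows = {lv: ilr_variables(wide.loc[lv].to_dict()) for lv in wide.index}
        resp_wide = pd.DataFrame.from_dict(rows, orient="index")
        obs = ilr_variables(observed)
        if response == "ilr3":
            keep = [v for v in resp_wide.columns if "," in v]
            resp_wide, obs = resp_wide[keep], {k: obs[k] for k in keep}
        elif response == "ilr2":
            keep = [v for v in resp_wide.columns if "," not in v]
            resp_wide, obs = resp_wide[keep], {k: obs[k] for k in keep}
    else:
        raise ValueError(f"unknown response {response!r}")

    if variables is not None:
        resp_wide = resp_wide[[v for v in variables if v in resp_wide.columns]]

    rows = []
    for var in resp_wide.columns:
        if var not in obs:
            continue
        fit = fit_level_regression(levels, resp_wide[var].to_numpy(), degree)
        try:
            est = estimate_hop_level(fit, obs[var])
        except ValueError:
            est = float("nan")
        rows.append((var, est, fit.r_squared, degree))
    out = pd.DataFrame(rows, columns=["variable", "estimate_percent", "r_squared", "degree"])
    # headline range over the homozygote variables only: heterozygote
    # responses are nearly flat in hop level, so inverting them is
    # meaningless (their fits have near-zero R^2)
    hom = set(HOMOZYGOTE_VARIABLES) | set(HOMOZYGOTE_ILR_VARIABLES)
    finite = out.loc[out["variable"].isin(hom), "estimate_percent"].dropna()
    if finite.empty:
        finite = out["estimate_percent"].dropna()
    out.attrs["range"] = (
        (float(finite.min()), float(finite.max())) if len(finite) else (float("nan"),) * 2
    )
    return out
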