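"""Information carried by the genotype about the habitat.

A polymorphic cue allele is informative about an individual's current
habitat because selection maintains different allele frequencies in the two
habitats: the conditional probability of being in habitat ``i`` given cue
allele ``x_k`` is ``q_ik = n_ik / (n_1k + n_2k)``.  This module quantifies
that information as the mutual information (in bits) between cue state and
habitat, extends it to continuous liabilities by binning, and fits logistic
regressions of habitat membership on the liability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .resident import conditional_habitat_probability

__all__ = [
    "InfoSummary",
    "LogisticFit",
    "mutual_information_bits",
    "empirical_cue_information",
    "liability_mutual_information",
    "habitat_logistic_regression",
    "information_ordering",
]

SLOPE_CAP = 50.0


def mutual_information_bits(joint: np.ndarray) -> float:
    """Mutual information (bits) of a joint count/probability table:
    ``MI = sum p(i,k) log2[p(i,k) / (p(i) p(k))]`` over its support."""
    joint = np.asarray(joint, dtype=float)
    if np.any(joint < 0):
        raise ValueError("joint table must be non-negative")
    total = joint.sum()
    if total <= 0:
        raise ValueError("joint table must have positive mass")
    p = joint / total
    pi = p.sum(axis=1, keepdims=True)
    pk = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log2(p / (pi * pk))
    return float(np.nansum(terms))


@dataclass(frozen=True)
class InfoSummary:
    """Habitat information in one population or equilibrium."""

    q: np.ndarray          # q[i, k]: habitat i given cue allele k (NaN if extinct)
    mi_bits: float         # mutual information cue <-> habitat
    counts: np.ndarray     # the underlying (2, 2) habitat x allele table


def empirical_cue_information(counts: np.ndarray) -> InfoSummary:
    """Conditional habitat probabilities and cue-habitat mutual information
    from a (habitat x allele) count table.

    An extinct allele contributes nothing to the MI (computed on the
    support); its ``q`` column is NaN.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (2, 2) or np.any(counts < 0):
        raise ValueError("counts must be a non-negative 2x2 table")
    if counts.sum() <= 0:
        raise ValueError("empty count table")
    q = conditional_habitat_probability(counts)
    return InfoSummary(q=q, mi_bits=mutual_information_bits(counts), counts=counts)


def liability_mutual_information(
    liabilities: np.ndarray, habitats: np.ndarray, bins: int = 20
) -> float:
    """Mutual information (bits) between the binned liability and habitat.

    Continuous genotype-phenotype architectures have no discrete cue state;
    the liability is discretized into ``bins`` equal-width bins over its
    observed range (a single bin if the range is degenerate).
    """
    liab = np.asarray(liabilities, dtype=float)
    hab = np.asarray(habitats)
    if liab.shape != hab.shape:
        raise ValueError("liabilities and habitat labels must align")
    lo, hi = float(liab.min()), float(liab.max())
    if hi - lo < 1e-12:
        return 0.0
    edges = np.linspace(lo, hi, bins + 1)
    idx = np.clip(np.digitize(liab, edges[1:-1]), 0, bins - 1)
    joint = np.zeros((2, bins))
    for i in range(2):
        joint[i] = np.bincount(idx[hab == i], minlength=bins)
    return mutual_information_bits(joint)


@dataclass(frozen=True)
class LogisticFit:
    """Logistic regression of habitat-1 membership on the liability."""

    intercept: float
    slope: float
    separated: bool  # complete/quasi-complete separation handled by capping

    def predict(self, liabilities: np.ndarray) -> np.ndarray:
        from scipy.special import expit

        return expit(self.intercept + self.slope * np.asarray(liabilities))


def habitat_logistic_regression(
    liabilities: np.ndarray, habitat_labels: np.ndarray
) -> LogisticFit:
    """Maximum-likelihood logistic fit of the habitat-1 indicator on the
    liability.

    Complete separation (habitats perfectly split by a liability threshold)
    makes the MLE slope diverge; it is then capped at +/-50 and the intercept
    re-estimated with the slope fixed (offset trick), with a warning.
    """
    import statsmodels.api as sm

    liab = np.asarray(liabilities, dtype=float)
    y = (np.asarray(habitat_labels) == 0).astype(float)  # habitat 1 indicator
    if y.min() == y.max():
        raise ValueError("both habitats must be represented")
    X = sm.add_constant(liab)
    separated = False
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        intercept, slope = float(fit.params[0]), float(fit.params[1])
        if not np.isfinite(slope) or abs(slope) > SLOPE_CAP:
            separated = True
    except Exception:
        separated = True
    if separated:
        # cap the slope and refit the intercept alone via an offset model
        rough = np.corrcoef(liab, y)[0, 1] if liab.std() > 0 else 1.0
        slope = SLOPE_CAP if rough >= 0 else -SLOPE_CAP
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit0 = sm.Logit(
                y, np.ones((len(y), 1)), offset=slope * liab
            ).fit(disp=0, maxiter=200)
        intercept = float(fit0.params[0])
        warnings.warn(
            "complete separation detected; slope capped at +/-50",
            RuntimeWarning,
            stacklevel=2,
        )
    return LogisticFit(intercept=intercept, slope=slope, separated=separated)


def information_ordering(runs: dict[str, list[float]]) -> pd.DataFrame:
    """Rank labelled groups of replicate MI values by mean information.

    ``runs`` maps a label (e.g. an architecture name) to the MI values of its
    replicate simulations; the result is sorted from most to least
    informative with the across-replicate standard error.
    """
    if len(runs) < 2:
        raise ValueError("need at least two groups to order")
    rows = []
    for label, values in runs.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ValueError(f"group {label!r} has no replicates")
        rows.append(
            dict(
                label=label,
                mean_mi=float(v.mean()),
                sd_mi=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                se_mi=float(v.std(ddof=1) / np.sqrt(v.size))
                if v.size > 1
                else 0.0,
                n=int(v.size),
            )
        )
    df = pd.DataFrame(rows).sort_values(
        "mean_mi", ascending=False, ignore_index=True
    )
    df["rank"] = np.arange(1, len(df) + 1)
    return df
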