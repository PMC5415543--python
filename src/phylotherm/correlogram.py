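"""Phylogenetic autocorrelograms: Moran's I over patristic-distance classes.

Phylogenetic signal — the tendency of closely related species to carry
similar trait values — is quantified here by computing Moran's I separately
for classes of species pairs binned by patristic distance. A positive I in
the first (closest-pairs) class that decays toward zero in farther classes is
the classic signature of trait similarity inherited from common ancestry.

For trait z (centred), binary within-class weights W with S0 = sum(W):

    I = (n / S0) * (z' W z) / (z' z)

Expected value under the random-labelling null is E[I] = -1/(n-1).
Significance is assessed by permuting trait values across species (the same
permutation applied to every class within an iteration) — robust for the
small species counts typical of comparative datasets; the analytic
normal-approximation variance is also reported for reference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .tree import DistanceMatrix

__all__ = ["DistanceClasses", "CorrelogramResult", "make_classes", "morans_i", "correlogram"]


@dataclass(frozen=True)
class DistanceClasses:
    """Partition of the off-diagonal species pairs into distance classes."""

    n_classes: int
    breaks: np.ndarray  # length n_classes + 1, increasing
    assignment: np.ndarray  # (n x n) int matrix, -1 on the diagonal

    def weights(self, k: int) -> np.ndarray:
        """Binary weight matrix selecting the pairs of class k."""
        return (self.assignment == k).astype(float)

    @property
    def pair_counts(self) -> np.ndarray:
        return np.array(
            [int((self.assignment == k).sum() // 2) for k in range(self.n_classes)]
        )


def make_classes(
    d: DistanceMatrix, n_classes: int = 3, scheme: str = "equal_frequency"
) -> DistanceClasses:
    """Bin the pairwise patristic distances into ``n_classes`` classes.

    equal_frequency places boundaries at quantiles of the pair-distance
    distribution so classes hold near-equal numbers of pairs (tied distances
    stay together); equal_width uses uniform bins over [min, max].
    """
    n = len(d.labels)
    iu = np.triu_indices(n, k=1)
    pair_d = d.values[iu]
    raw_uniq, raw_counts = np.unique(pair_d, return_counts=True)
    # merge floating-point near-ties into single tie blocks
    tol = 1e-9 * max(float(raw_uniq[-1]), 1.0)
    block = np.concatenate([[0], np.cumsum(np.diff(raw_uniq) > tol)])
    uniq = np.array([raw_uniq[block == b].mean() for b in range(block[-1] + 1)])
    counts = np.array([raw_counts[block == b].sum() for b in range(block[-1] + 1)])
    if n_classes < 1:
        raise ValidationError("n_classes must be >= 1")
    if n_classes > len(uniq):
        raise ValidationError(
            f"cannot form {n_classes} nonempty classes from {len(uniq)} distinct "
            "pair distances; use fewer classes"
        )
    if scheme == "equal_frequency":
        # partition the sorted unique distances into contiguous blocks with
        # near-equal cumulative pair counts; tied distances stay together
        cum = np.cumsum(counts)
        total = cum[-1]
        cuts: list[int] = []  # index of the last unique value in each class
        prev = -1
        for k in range(1, n_classes):
            target = k * total / n_classes
            j = int(np.searchsorted(cum, target, side="left"))
            if j > 0 and abs(cum[j - 1] - target) <= abs(cum[min(j, len(cum) - 1)] - target):
                j -= 1  # cutting before the tie block lands nearer the target
            lo = prev + 1
            hi = len(uniq) - 1 - (n_classes - k)  # leave >=1 value per later class
            j = min(max(j, lo), hi)
            cuts.append(j)
            prev = j
        inner = [(uniq[c] + uniq[c + 1]) / 2 for c in cuts]
        breaks = np.array([uniq[0], *inner, uniq[-1]])
    elif scheme == "equal_width":
        breaks = np.linspace(pair_d.min(), pair_d.max(), n_classes + 1)
    else:
        raise ValidationError(f"unknown scheme {scheme!r}")
    idx = np.searchsorted(breaks, d.values, side="right") - 1
    idx = np.clip(idx, 0, n_classes - 1)
    np.fill_diagonal(idx, -1)
    classes = DistanceClasses(n_classes, np.asarray(breaks, dtype=float), idx)
    if np.any(classes.pair_counts == 0):
        raise ValidationError("a distance class is empty; use fewer classes")
    return classes


def _prepare_trait(trait: np.ndarray) -> np.ndarray:
    z = np.asarray(trait, dtype=float)
    if z.ndim != 1 or len(z) < 3:
        raise ValidationError("trait must be a 1-d vector over >= 3 species")
    z = z - z.mean()
    if np.allclose(z, 0):
        raise UndefinedStatisticError("trait has zero variance; Moran's I undefined")
    return z


def morans_i(trait: np.ndarray, weights: np.ndarray) -> float:
    """Moran's I for one binary weight matrix (one distance class)."""
    z = _prepare_trait(trait)
    W = np.asarray(weights, dtype=float)
    n = len(z)
    if W.shape != (n, n) or not np.allclose(W, W.T) or np.any(np.diag(W) != 0):
        raise ValidationError("weights must be symmetric with zero diagonal")
    s0 = W.sum()
    if s0 == 0:
        raise ValidationError("weight matrix is all zero")
    return float((n / s0) * (z @ W @ z) / (z @ z))


def _analytic_variance(W: np.ndarray, n: int) -> float:
    """Variance of I under the normality null (reference only)."""
    s0 = W.sum()
    s1 = 0.5 * np.sum((W + W.T) ** 2)
    s2 = np.sum((W.sum(axis=0) + W.sum(axis=1)) ** 2)
    ei = -1.0 / (n - 1)
    var = (n**2 * s1 - n * s2 + 3 * s0**2) / (s0**2 * (n**2 - 1)) - ei**2
    return float(max(var, 0.0))


@dataclass(frozen=True)
class CorrelogramResult:
    """Per-class Moran's I with permutation p-values and jackknife SEs."""

    trait_name: str
    classes: DistanceClasses
    I: np.ndarray
    expected_I: float
    p_values: np.ndarray
    se_jackknife: np.ndarray
    var_analytic: np.ndarray
    n_pairs: np.ndarray
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        b = self.classes.breaks
        return pd.DataFrame(
            {
                "class": np.arange(1, self.classes.n_classes + 1),
                "break_low": b[:-1],
                "break_high": b[1:],
                "n_pairs": self.n_pairs,
                "I": self.I,
                "expected_I": self.expected_I,
                "se_jackknife": self.se_jackknife,
                "p": self.p_values,
            }
        )

    def summary(self) -> str:
        header = f"Phylogenetic correlogram: {self.trait_name} ({self.n_perm} permutations)"
        return header + "\n" + self.to_frame().to_string(index=False, float_format="%.4f")

    def plot(self, ax=None):
        """Moran's I against distance-class midpoint, with jackknife error bars."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mids = 0.5 * (self.classes.breaks[:-1] + self.classes.breaks[1:])
        ax.errorbar(mids, self.I, yerr=self.se_jackknife, marker="o", capsize=3)
        ax.axhline(0.0, color="grey", lw=0.8)
        ax.set_xlabel("patristic distance (class midpoint)")
        ax.set_ylabel("Moran's I")
        ax.set_title(self.trait_name)
        return ax


def _class_moran_vector(z: np.ndarray, weight_list: list[np.ndarray]) -> np.ndarray:
    n = len(z)
    denom = z @ z
    return np.array([(n / W.sum()) * (z @ W @ z) / denom for W in weight_list])


def correlogram(
    trait: np.ndarray,
    d: DistanceMatrix,
    n_classes: int = 3,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    scheme: str = "equal_frequency",
    trait_name: str = "trait",
) -> CorrelogramResult:
    """Moran's I per distance class, with two-sided permutation p-values.

    One trait permutation per iteration is shared by every class, and the
    p-value counts permuted |I - E[I]| at least as extreme as observed:
    p = (1 + #extreme) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    z = _prepare_trait(trait)
    n = len(z)
    if len(d.labels) != n:
        raise ValidationError("trait length does not match distance matrix")
    classes = make_classes(d, n_classes=n_classes, scheme=scheme)
    weights = [classes.weights(k) for k in range(n_classes)]
    ei = -1.0 / (n - 1)
    obs = _class_moran_vector(z, weights)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    Zp = z[perms]  # (n_perm, n)
    denom = float(z @ z)  # invariant under permutation
    extreme = np.zeros(n_classes, dtype=int)
    perm_I = np.empty((n_perm, n_classes))
    for k, W in enumerate(weights):
        quad = np.einsum("pi,ij,pj->p", Zp, W, Zp)
        perm_I[:, k] = (n / W.sum()) * quad / denom
        extreme[k] = int(np.sum(np.abs(perm_I[:, k] - ei) >= np.abs(obs[k] - ei) - 1e-12))
    p = (1 + extreme) / (n_perm + 1)

    # jackknife-over-species SE per class (drop one species, recompute I)
    se = np.empty(n_classes)
    for k, W in enumerate(weights):
        vals = []
        for i in range(n):
            keep = np.arange(n) != i
            Wk = W[np.ix_(keep, keep)]
            if Wk.sum() == 0:
                continue
            zi = trait[keep] - np.mean(trait[keep])
            if np.allclose(zi, 0):
                continue
            m = len(zi)
            vals.append((m / Wk.sum()) * (zi @ Wk @ zi) / (zi @ zi))
        vals = np.asarray(vals)
        m = len(vals)
        se[k] = np.sqrt((m - 1) / m * np.sum((vals - vals.mean()) ** 2)) if m > 1 else np.nan

    return CorrelogramResult(
        trait_name=trait_name,
        classes=classes,
        I=obs,
        expected_I=ei,
        p_values=p,
        se_jackknife=se,
        var_analytic=np.array([_analytic_variance(W, n) for W in weights]),
        n_pairs=classes.pair_counts,
        n_perm=n_perm,
    )
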