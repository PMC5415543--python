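"""Phylogenetic generalized least squares, phylogenetic ANOVA and post hoc tests.

The comparative question — does zoogeographical province, or microhabitat
temperature, shape the evolution of a critical thermal limit? — is answered
by regression models whose residuals are correlated according to the
phylogeny. Three residual structures are supported:

* identity: the conventional, phylogeny-free model;
* BM: Brownian-motion covariance (shared root-to-MRCA path length);
* OU: Ornstein-Uhlenbeck correlation exp(-alpha d_ij), whose selection
  strength alpha is profiled out by maximum likelihood.

Fitting is by ML throughout (not REML), so profile-alpha likelihoods are
comparable across fixed-effects designs. Estimation whitens the model with
the Cholesky factor of C:

    beta = (X' C^-1 X)^-1 X' C^-1 y
    sigma2_ml = RSS_whitened / n
    loglik = -1/2 [ n log(2 pi sigma2_ml) + log|C| + n ]

`phyl_anova` keeps the classical one-way F statistic but replaces its null
distribution by F values recomputed on Brownian-motion simulations along the
tree; `posthoc_holm` does the same for pairwise comparisons and applies the
Holm-Bonferroni step-down correction across the family of pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import DesignError, UnidentifiableError, ValidationError
from .tree import CovarianceStructure, Phylogeny, covariance, patristic_distances

__all__ = [
    "DesignInfo",
    "build_design",
    "PGLS",
    "PGLSResults",
    "AnovaTable",
    "PosthocResult",
    "gls_fit",
    "fit_ou_alpha",
    "anova",
    "phyl_anova",
    "posthoc_holm",
    "holm_adjust",
    "simulate_bm_on_structure",
]

ALPHA_GRID = np.logspace(-4, 3, 61)
FLAT_PROFILE_TOL = 1e-8
ZERO_RSS_TOL = 1e-12


# ---------------------------------------------------------------------------
# design matrices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DesignInfo:
    """Design matrix plus term bookkeeping (name -> column slice)."""

    X: np.ndarray
    column_names: tuple[str, ...]
    terms: tuple[tuple[str, slice], ...]  # ordered, includes "Intercept"

    @property
    def term_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.terms)

    def columns_for(self, names: Sequence[str]) -> np.ndarray:
        cols: list[int] = []
        for name, sl in self.terms:
            if name in names:
                cols.extend(range(sl.start, sl.stop))
        return self.X[:, cols]


def build_design(
    data: pd.DataFrame,
    factors: Sequence[str] = (),
    covariates: Sequence[str] = (),
    interactions: Sequence[tuple[str, str]] = (),
) -> DesignInfo:
    """Treatment-coded design matrix: intercept, factor dummies (first level
    as reference, levels sorted), covariates, then factor x covariate
    interaction columns."""
    n = len(data)
    blocks = [np.ones((n, 1))]
    names = ["Intercept"]
    terms: list[tuple[str, slice]] = [("Intercept", slice(0, 1))]
    pos = 1
    level_map: dict[str, list[str]] = {}
    for f in factors:
        levels = sorted(map(str, pd.unique(data[f].astype(str))))
        level_map[f] = levels
        dummies = np.column_stack(
            [(data[f].astype(str) == lev).to_numpy(float) for lev in levels[1:]]
        )
        blocks.append(dummies)
        names += [f"{f}[{lev}]" for lev in levels[1:]]
        terms.append((f, slice(pos, pos + dummies.shape[1])))
        pos += dummies.shape[1]
    for c in covariates:
        blocks.append(data[c].to_numpy(float).reshape(-1, 1))
        names.append(c)
        terms.append((c, slice(pos, pos + 1)))
        pos += 1
    for f, c in interactions:
        levels = level_map.get(f) or sorted(map(str, pd.unique(data[f].astype(str))))
        cov = data[c].to_numpy(float)
        cols = np.column_stack(
            [(data[f].astype(str) == lev).to_numpy(float) * cov for lev in levels[1:]]
        )
        blocks.append(cols)
        names += [f"{f}[{lev}]:{c}" for lev in levels[1:]]
        terms.append((f"{f}:{c}", slice(pos, pos + cols.shape[1])))
        pos += cols.shape[1]
    X = np.hstack(blocks)
    return DesignInfo(X, tuple(names), tuple(terms))


# ---------------------------------------------------------------------------
# core GLS machinery
# ---------------------------------------------------------------------------

def _whiten(C: np.ndarray):
    L = linalg.cholesky(C, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    return L, logdet


def _aliased_columns(Xw: np.ndarray, names: Sequence[str]) -> list[str]:
    _, R, piv = linalg.qr(Xw, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(Xw.shape) * np.finfo(float).eps if diag.size else 0.0
    return [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]


def _gls_core(y: np.ndarray, X: np.ndarray, C: np.ndarray, names=None):
    """Whitened least squares; returns estimates and likelihood pieces."""
    n, p = X.shape
    if n <= p:
        raise DesignError(f"n={n} does not exceed the number of parameters p={p}")
    L, logdet = _whiten(C)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    rank = np.linalg.matrix_rank(Xw)
    if rank < p:
        aliased = _aliased_columns(Xw, names or [f"x{i}" for i in range(p)])
        raise DesignError("design matrix is rank deficient", aliased=aliased)
    beta, _, _, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta
    rss = float(resid_w @ resid_w)
    scale_ref = max(float(yw @ yw), 1.0)
    if rss <= ZERO_RSS_TOL * scale_ref:
        raise UnidentifiableError(
            "zero residual variance (response lies in the column space of the "
            "design); the likelihood is degenerate"
        )
    sigma2_ml = rss / n
    loglik = -0.5 * (n * np.log(2 * np.pi * sigma2_ml) + logdet + n)
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    return {
        "beta": beta,
        "rss": rss,
        "sigma2_ml": sigma2_ml,
        "loglik": loglik,
        "xtx_inv": xtx_inv,
        "resid_w": resid_w,
        "yw": yw,
        "Xw": Xw,
        "logdet": logdet,
        "df_resid": n - p,
    }


def _whitened_rss(y, X, C) -> tuple[float, int]:
    """RSS and rank of a possibly rank-deficient submodel in the whitened space."""
    L, _ = _whiten(C)
    yw = linalg.solve_triangular(L, y, lower=True)
    Xw = linalg.solve_triangular(L, X, lower=True)
    beta, _, rank, _ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    return float(r @ r), int(rank)


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class AnovaTable:
    """F table: one row per model term (plus residual bookkeeping)."""

    frame: pd.DataFrame
    kind: str  # "sequential" | "marginal" | "phyl_anova"

    def __getitem__(self, term):
        return self.frame.loc[term]

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def summary(self) -> str:
        return f"ANOVA ({self.kind})\n" + self.frame.to_string(float_format="%.4f")


@dataclass
class PosthocResult:
    """Pairwise comparisons with simulation p-values and Holm adjustment."""

    frame: pd.DataFrame  # pair, estimate, t, p_sim, p_holm
    n_sim: int

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def summary(self) -> str:
        return (
            f"Phylogenetic-simulation post hoc ({self.n_sim} simulations, Holm-adjusted)\n"
            + self.frame.to_string(index=False, float_format="%.4f")
        )


class PGLSResults:
    """Fitted PGLS model: coefficients, alpha (OU), likelihood, diagnostics."""

    def __init__(self, model: "PGLS", structure: CovarianceStructure, core: dict,
                 alpha_profile: pd.DataFrame | None = None,
                 alpha_at_boundary: bool = False, alpha_flat: bool = False,
                 alpha_gap_to_identity: float | None = None):
        self.model = model
        self.structure = structure
        self.params = pd.Series(core["beta"], index=model.design.column_names)
        self.sigma2 = core["sigma2_ml"]
        self.llf = core["loglik"]
        self.rss_whitened = core["rss"]
        self.df_resid = core["df_resid"]
        self._xtx_inv = core["xtx_inv"]
        self.resid_whitened = core["resid_w"]
        self.fittedvalues = pd.Series(
            model.design.X @ core["beta"], index=model.species
        )
        self.resid = pd.Series(model.y - self.fittedvalues.to_numpy(), index=model.species)
        scale = core["rss"] / core["df_resid"]
        self.scale = scale
        self.bse = pd.Series(np.sqrt(np.diag(self._xtx_inv) * scale),
                             index=model.design.column_names)
        self.tvalues = self.params / self.bse
        self.pvalues = pd.Series(
            2 * stats.t.sf(np.abs(self.tvalues), self.df_resid),
            index=model.design.column_names,
        )
        self.alpha = structure.alpha
        self.alpha_profile = alpha_profile
        self.alpha_at_boundary = alpha_at_boundary
        self.alpha_flat = alpha_flat
        #: loglik advantage of alpha-hat over the identity (alpha -> inf) limit
        self.alpha_gap_to_identity = alpha_gap_to_identity

    # ----- F tables -----
    def anova(self, typ: Literal["sequential", "marginal"] = "sequential") -> AnovaTable:
        return anova(self, typ=typ)

    def summary(self) -> str:
        m = self.model
        lines = [
            f"PGLS fit: {m.response_name} ~ {' + '.join(n for n in m.design.term_names if n != 'Intercept') or '1'}",
            f"structure: {self.structure.kind}"
            + (f" (alpha = {self.alpha:.4g}"
               + (", boundary" if self.alpha_at_boundary else "") + ")"
               if self.alpha is not None else ""),
            f"n = {m.nobs}, loglik = {self.llf:.4f}, sigma2(ML) = {self.sigma2:.4f}",
            "-" * 60,
            pd.DataFrame(
                {"coef": self.params, "se": self.bse, "t": self.tvalues, "p": self.pvalues}
            ).to_string(float_format="%.4f"),
        ]
        return "\n".join(lines)


class PGLS:
    """Generalized least squares model with a phylogenetic residual structure.

    Parameters
    ----------
    y : response values, ordered like ``species``
    design : DesignInfo (use :func:`build_design` or ``from_dataframe``)
    species : species labels giving the row order
    tree : Phylogeny, required for BM/OU structures and alpha estimation
    """

    def __init__(self, y, design: DesignInfo, species: Sequence[str],
                 tree: Phylogeny | None = None, response_name: str = "y"):
        self.y = np.asarray(y, dtype=float)
        self.design = design
        self.species = tuple(species)
        self.tree = tree
        self.response_name = response_name
        if len(self.y) != design.X.shape[0] or len(self.species) != len(self.y):
            raise ValidationError("y, design and species must align")
        if tree is not None and set(self.species) - set(tree.tips):
            missing = sorted(set(self.species) - set(tree.tips))
            raise ValidationError(f"species not in tree: {', '.join(missing)}")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        response: str,
        factors: Sequence[str] = (),
        covariates: Sequence[str] = (),
        interactions: Sequence[tuple[str, str]] = (),
        tree: Phylogeny | None = None,
        species_col: str = "species",
    ) -> "PGLS":
        design = build_design(data, factors, covariates, interactions)
        return cls(
            data[response].to_numpy(float),
            design,
            data[species_col].astype(str).tolist(),
            tree=tree,
            response_name=response,
        )

    @property
    def nobs(self) -> int:
        return len(self.y)

    def _structure(self, structure, alpha) -> CovarianceStructure:
        if isinstance(structure, CovarianceStructure):
            return self._reorder(structure)
        if structure == "identity":
            return CovarianceStructure("identity", self.species, np.eye(self.nobs))
        if self.tree is None:
            raise ValidationError(f"structure {structure!r} needs a tree")
        kind = {"bm": "BM", "ou": "OU"}.get(str(structure).lower())
        if kind is None:
            raise ValidationError(f"unknown structure {structure!r}")
        return self._reorder(covariance(self.tree, kind, alpha=alpha))

    def _reorder(self, struct: CovarianceStructure) -> CovarianceStructure:
        if tuple(struct.labels) == self.species:
            return struct
        idx = [struct.labels.index(s) for s in self.species]
        return CovarianceStructure(
            struct.kind, self.species, struct.C[np.ix_(idx, idx)], alpha=struct.alpha
        )

    def fit(self, structure="identity", alpha: float | None = None) -> PGLSResults:
        """Fit with a fixed correlation structure ("identity", "bm", "ou" at a
        given alpha, or an explicit CovarianceStructure)."""
        if structure == "ou" and alpha is None:
            return self.fit_ou()
        struct = self._structure(structure, alpha)
        core = _gls_core(self.y, self.design.X, struct.C, self.design.column_names)
        return PGLSResults(self, struct, core)

    def fit_ou(self) -> PGLSResults:
        """Profile the OU selection strength alpha by maximum likelihood.

        A log-spaced grid (1e-4 ... 1e3, 61 points) is scanned and the best
        point refined by bounded golden-section search between its grid
        neighbours, to relative tolerance 1e-6 in alpha. Boundary maxima and
        flat profiles are flagged rather than hidden.
        """
        if self.tree is None:
            raise ValidationError("OU estimation needs a tree")
        d = patristic_distances(self.tree).submatrix(self.species).values

        def negll(log_a: float) -> float:
            C = np.exp(-np.exp(log_a) * d)
            try:
                return -_gls_core(self.y, self.design.X, C, self.design.column_names)["loglik"]
            except np.linalg.LinAlgError:
                return np.inf

        grid = ALPHA_GRID
        lls = np.array([-negll(np.log(a)) for a in grid])
        best = int(np.argmax(lls))
        flat = bool(np.ptp(lls[np.isfinite(lls)]) < FLAT_PROFILE_TOL)
        at_boundary = best in (0, len(grid) - 1)
        if flat:
            warnings.warn("alpha profile is flat; alpha is unidentifiable", stacklevel=2)
            alpha_hat = grid[-1]
            at_boundary = True
        elif at_boundary:
            alpha_hat = grid[best]
        else:
            res = optimize.minimize_scalar(
                negll,
                bounds=(np.log(grid[best - 1]), np.log(grid[best + 1])),
                method="bounded",
                options={"xatol": 1e-6},
            )
            alpha_hat = float(np.exp(res.x))
            # an interior argmax in a flat tail is the identity limit in disguise
            if -negll(res.x) - lls[-1] < 1e-6:
                at_boundary = True
        struct = CovarianceStructure(
            "OU", self.species, np.exp(-alpha_hat * d), alpha=alpha_hat
        )
        core = _gls_core(self.y, self.design.X, struct.C, self.design.column_names)
        profile = pd.DataFrame({"alpha": grid, "loglik": lls})
        gap = float(core["loglik"] - lls[-1])
        return PGLSResults(self, struct, core, alpha_profile=profile,
                           alpha_at_boundary=at_boundary, alpha_flat=flat,
                           alpha_gap_to_identity=gap)


# ---------------------------------------------------------------------------
# functional wrappers matching the operation-level API
# ---------------------------------------------------------------------------

def gls_fit(y, X, C, names=None, species=None) -> PGLSResults:
    """One-shot GLS fit of y on a raw design matrix under covariance C."""
    X = np.asarray(X, dtype=float)
    if isinstance(C, CovarianceStructure):
        struct = C
        Cmat = C.C
    else:
        Cmat = np.asarray(C, dtype=float)
        struct = CovarianceStructure("BM" if not np.allclose(Cmat, np.eye(len(Cmat))) else "identity",
                                     tuple(species or map(str, range(len(Cmat)))), Cmat)
    names = tuple(names or [f"x{i}" for i in range(X.shape[1])])
    design = DesignInfo(X, names, tuple((nm, slice(i, i + 1)) for i, nm in enumerate(names)))
    species = tuple(species or struct.labels)
    model = PGLS(y, design, species)
    core = _gls_core(model.y, X, Cmat, names)
    return PGLSResults(model, struct, core)


def fit_ou_alpha(y, X_or_design, tree: Phylogeny, names=None, species=None) -> PGLSResults:
    """Profile-ML estimate of the OU selection strength for y on X."""
    if isinstance(X_or_design, DesignInfo):
        design = X_or_design
    else:
        X = np.asarray(X_or_design, dtype=float)
        names = tuple(names or [f"x{i}" for i in range(X.shape[1])])
        design = DesignInfo(X, names, tuple((nm, slice(i, i + 1)) for i, nm in enumerate(names)))
    model = PGLS(y, design, tuple(species or tree.tips), tree=tree)
    return model.fit_ou()


def anova(fit: PGLSResults, typ: Literal["sequential", "marginal"] = "sequential") -> AnovaTable:
    """F table for a fitted PGLS model.

    sequential (type I): terms enter in design order; each term's SS is the
    drop in whitened RSS when it is added. marginal (drop-one): each term's
    SS is the rise in whitened RSS when it alone is removed; main effects are
    tested in the model without interactions involving them.
    """
    model = fit.model
    C = fit.structure.C
    y = model.y
    info = model.design
    terms = [t for t in info.terms if t[0] != "Intercept"]
    if not terms:
        raise ValidationError("model has no non-intercept terms to test")
    rss_full, rank_full = _whitened_rss(y, info.X, C)
    n = model.nobs
    df_den = n - rank_full
    if df_den == 0:
        raise DesignError("saturated model: zero residual degrees of freedom")
    mse = rss_full / df_den

    rows = []
    if typ == "sequential":
        included = ["Intercept"]
        rss_prev, rank_prev = _whitened_rss(y, info.columns_for(included), C)
        for name, _ in terms:
            included.append(name)
            rss_cur, rank_cur = _whitened_rss(y, info.columns_for(included), C)
            df = rank_cur - rank_prev
            ss = rss_prev - rss_cur
            F = (ss / df) / mse if df > 0 else np.nan
            rows.append((name, df, df_den, ss, F, stats.f.sf(F, df, df_den)))
            rss_prev, rank_prev = rss_cur, rank_cur
    elif typ == "marginal":
        inter_names = {nm for nm, _ in terms if ":" in nm}
        for name, _ in terms:
            if ":" in name:
                base = [nm for nm, _ in info.terms]
            else:
                # drop interactions containing this main effect before testing it
                base = [nm for nm, _ in info.terms
                        if not (nm in inter_names and name in nm.split(":"))]
            rss_with, rank_with = _whitened_rss(y, info.columns_for(base), C)
            without = [nm for nm in base if nm != name]
            rss_wo, rank_wo = _whitened_rss(y, info.columns_for(without), C)
            df = rank_with - rank_wo
            ss = rss_wo - rss_with
            F = (ss / df) / mse if df > 0 else np.nan
            rows.append((name, df, df_den, ss, F, stats.f.sf(F, df, df_den)))
    else:
        raise ValidationError(f"unknown anova type {typ!r}")

    frame = pd.DataFrame(
        rows, columns=["term", "df_num", "df_den", "SS", "F", "p_analytic"]
    ).set_index("term")
    frame.attrs["rss_resid"] = rss_full
    return AnovaTable(frame, kind=typ)


# ---------------------------------------------------------------------------
# simulation-based phylogenetic ANOVA and post hoc tests
# ---------------------------------------------------------------------------

def _group_indicator(group: Sequence) -> tuple[np.ndarray, list[str]]:
    labels = sorted(map(str, pd.unique(pd.Series(group).astype(str))))
    G = np.column_stack([(pd.Series(group).astype(str) == g).to_numpy(float) for g in labels])
    return G, labels


def _oneway_f(Y: np.ndarray, G: np.ndarray) -> np.ndarray:
    """Classical one-way ANOVA F, vectorised over rows of Y (n_sim x n)."""
    Y = np.atleast_2d(Y)
    n = Y.shape[1]
    k = G.shape[1]
    counts = G.sum(axis=0)
    means = (Y @ G) / counts
    grand = Y.mean(axis=1, keepdims=True)
    ssb = ((means - grand) ** 2 * counts).sum(axis=1)
    sst = ((Y - grand) ** 2).sum(axis=1)
    ssw = sst - ssb
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / (k - 1)) / (ssw / (n - k))
    return F


def _bm_rate_from_residuals(y: np.ndarray, X: np.ndarray, C: np.ndarray) -> float:
    """ML Brownian rate of the residuals from the group-mean model."""
    core = _gls_core(y, X, C)
    return core["sigma2_ml"]


def simulate_bm_on_structure(C: np.ndarray, sigma2: float, n_sim: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Draw n_sim zero-mean Brownian trait vectors with covariance sigma2*C."""
    L = linalg.cholesky(sigma2 * C, lower=True)
    return rng.standard_normal((n_sim, C.shape[0])) @ L.T


def phyl_anova(y, group, tree: Phylogeny, n_sim: int = 1000,
               seed: int | np.random.Generator = 0,
               species: Sequence[str] | None = None) -> AnovaTable:
    """One-way ANOVA with a Brownian-motion simulation null on the tree.

    The F statistic is the ordinary between/within ratio; the phylogeny
    enters only through its null distribution: traits are simulated under BM
    (rate = ML estimate from the residuals of the group-mean model) and F is
    recomputed per simulation. p_simulated = (1 + #{F_sim >= F_obs})/(n_sim+1).
    """
    y = np.asarray(y, dtype=float)
    species = tuple(species or tree.tips)
    if set(species) - set(tree.tips):
        raise ValidationError("species not in tree")
    G, labels = _group_indicator(group)
    if G.shape[1] < 2:
        raise ValidationError("need at least 2 groups")
    if np.allclose(y, y.mean()):
        raise UnidentifiableError("zero-variance trait: F undefined")
    C = _bm_sub(tree, species)
    F_obs = float(_oneway_f(y, G)[0])
    sigma2 = _bm_rate_from_residuals(y, G, C)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Ysim = simulate_bm_on_structure(C, sigma2, n_sim, rng)
    F_sim = _oneway_f(Ysim, G)
    p_sim = (1 + int(np.sum(F_sim >= F_obs - 1e-12))) / (n_sim + 1)
    k = G.shape[1]
    n = len(y)
    frame = pd.DataFrame(
        {
            "df_num": [k - 1],
            "df_den": [n - k],
            "F": [F_obs],
            "p_analytic": [float(stats.f.sf(F_obs, k - 1, n - k))],
            "p_simulated": [p_sim],
        },
        index=pd.Index(["group"], name="term"),
    )
    return AnovaTable(frame, kind="phyl_anova")


def _bm_sub(tree: Phylogeny, species: Sequence[str]) -> np.ndarray:
    struct = covariance(tree, "BM")
    idx = [struct.labels.index(s) for s in species]
    return struct.C[np.ix_(idx, idx)]


def holm_adjust(p: Sequence[float]) -> np.ndarray:
    """Holm-Bonferroni step-down adjustment with enforced monotonicity."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p[i])
        adj[i] = min(running, 1.0)
    return adj


def posthoc_holm(y, group, tree: Phylogeny, n_sim: int = 1000,
                 seed: int | np.random.Generator = 0,
                 covariate=None, species: Sequence[str] | None = None) -> PosthocResult:
    """Pairwise province comparisons with BM-simulation p-values, Holm-adjusted.

    t statistics are classical contrasts of (covariate-adjusted) group means;
    their null distribution comes from Brownian simulations along the tree,
    exactly as in :func:`phyl_anova`. When ``covariate`` is given the
    comparison is between adjusted means from the parallel-slopes ANCOVA
    model (group + covariate), i.e. differences at a common covariate value.
    """
    y = np.asarray(y, dtype=float)
    species = tuple(species or tree.tips)
    G, labels = _group_indicator(group)
    k = G.shape[1]
    if k < 2:
        raise ValidationError("need at least 2 groups")
    X = G.copy()  # cell-means coding: coefficients are the group means
    if covariate is not None:
        X = np.hstack([X, np.asarray(covariate, dtype=float).reshape(-1, 1)])
    n, p = X.shape
    pinv = np.linalg.pinv(X)
    xtx_inv = np.linalg.inv(X.T @ X)
    C = _bm_sub(tree, species)

    def pairwise_t(Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Y = np.atleast_2d(Y)
        B = Y @ pinv.T
        resid = Y - B @ X.T
        s2 = (resid**2).sum(axis=1) / (n - p)
        ts, ds = [], []
        for i, j in combinations(range(k), 2):
            c = np.zeros(p)
            c[i], c[j] = 1.0, -1.0
            diff = B @ c
            se = np.sqrt(s2 * (c @ xtx_inv @ c))
            ts.append(diff / se)
            ds.append(diff)
        return np.array(ts).T, np.array(ds).T  # (n_rep, n_pairs)

    t_obs, d_obs = pairwise_t(y)
    t_obs, d_obs = t_obs[0], d_obs[0]
    sigma2 = _bm_rate_from_residuals(y, X, C)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Ysim = simulate_bm_on_structure(C, sigma2, n_sim, rng)
    t_sim, _ = pairwise_t(Ysim)
    p_sim = (1 + np.sum(np.abs(t_sim) >= np.abs(t_obs)[None, :] - 1e-12, axis=0)) / (n_sim + 1)
    p_holm = holm_adjust(p_sim)
    pairs = [f"{labels[i]} - {labels[j]}" for i, j in combinations(range(k), 2)]
    frame = pd.DataFrame(
        {"pair": pairs, "estimate": d_obs, "t": t_obs, "p_sim": p_sim, "p_holm": p_holm}
    )
    return PosthocResult(frame, n_sim=n_sim)
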