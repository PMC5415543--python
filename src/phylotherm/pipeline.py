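"""End-to-end comparative analysis of the packaged crab dataset.

Runs, in order: province summaries (means and SEMs of MHT, LL50, UL50),
phylogenetic correlograms for the three traits, a simulation-based
phylogenetic ANOVA of MHT on province, PGLS ANCOVA under OU correlation for
each critical limit (province + MHT + interaction, with the selection
strength alpha profiled by ML), and phylogenetic-simulation Holm post hoc
comparisons. Everything is deterministic given the seed; the report bundle
carries a provenance block (package versions, seed, configuration hash).

Branch-length-dependent statistics computed on the packaged surrogate tree
(correlogram I values, alpha estimates, ANCOVA F values) are flagged in the
report as non-comparable to values from the unpublished molecular tree; the
province summaries and the classical ANOVA F statistic do not depend on the
tree at all.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pgls as pg
from .correlogram import correlogram as _correlogram
from .datasets import PROVINCE_TM, load_surrogate_tree, load_trait_table
from .errors import PhylothermError, ValidationError
from .tree import Phylogeny, patristic_distances, prune

__all__ = ["ProvinceSummary", "summarize_provinces", "run_paper_pipeline", "round_half_away"]

TRAITS = ("MHT", "LL50", "UL50")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention used for report display)."""
    factor = 10.0**decimals
    scaled = x * factor
    return float(np.sign(scaled) * np.floor(np.abs(scaled) + 0.5) / factor)


@dataclass(frozen=True)
class ProvinceSummary:
    """Per-province species-level means and SEMs of the three traits."""

    frame: pd.DataFrame  # index: province; columns: n_species, <trait>_mean/_sem

    def mean(self, province: str, trait: str) -> float:
        return float(self.frame.loc[province, f"{trait}_mean"])

    def sem(self, province: str, trait: str) -> float:
        return float(self.frame.loc[province, f"{trait}_sem"])

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def summary(self) -> str:
        return "Province summaries (species-level means +/- SEM)\n" + self.frame.to_string(
            float_format="%.3f"
        )


def summarize_provinces(traits: pd.DataFrame) -> ProvinceSummary:
    """Unweighted species-level means and SEMs per province and trait.

    Each species contributes one value per trait (its own mean), so a
    province's mean is the arithmetic mean over its member species and the
    SEM is sd/sqrt(n_species). Single-species provinces get SEM = NaN.
    """
    known = set(PROVINCE_TM)
    unknown = set(traits["province"].astype(str)) - known
    if unknown:
        raise ValidationError(f"unknown province labels: {', '.join(sorted(unknown))}")
    rows = {}
    for prov, sub in traits.groupby("province"):
        row = {"n_species": len(sub), "T_m": PROVINCE_TM[str(prov)]}
        for t in TRAITS:
            vals = sub[t].to_numpy(float)
            row[f"{t}_mean"] = float(vals.mean())
            row[f"{t}_sem"] = (
                float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            )
        rows[str(prov)] = row
    order = [p for p in PROVINCE_TM if p in rows]
    return ProvinceSummary(pd.DataFrame.from_dict(rows, orient="index").loc[order])


def _stage(name: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PhylothermError):
                raise PhylothermError(f"pipeline stage '{name}' failed: {exc}") from exc
            if isinstance(exc, PhylothermError):
                exc.args = (f"pipeline stage '{name}': {exc}",)
            return False

    return _Ctx()


def run_paper_pipeline(
    traits: pd.DataFrame | None = None,
    tree: Phylogeny | None = None,
    seed: int = 1,
    n_perm: int = 999,
    n_sim: int = 1000,
    n_classes: int = 3,
    out_dir: str | None = None,
) -> dict:
    """Full analysis chain on a trait table and tree (defaults: packaged data).

    Returns a report bundle (dict). If ``out_dir`` is given, the bundle is
    additionally written as a Markdown report plus TSV tables — only after
    every stage has succeeded, so no partial bundles land on disk.
    """
    if traits is None:
        traits = load_trait_table()
    if tree is None:
        tree = load_surrogate_tree()
    species = traits["species"].astype(str).tolist()
    missing = sorted(set(species) - set(tree.tips))
    if missing:
        raise ValidationError(f"tree is missing species: {', '.join(missing)}")
    if set(tree.tips) - set(species):
        tree = prune(tree, species)

    rngs = np.random.SeedSequence(seed).spawn(3)
    rng_corr = np.random.default_rng(rngs[0])
    rng_anova = np.random.default_rng(rngs[1])
    rng_posthoc = np.random.default_rng(rngs[2])

    bundle: dict = {"seed": seed}
    with _stage("province_summary"):
        bundle["province_summary"] = summarize_provinces(traits)

    with _stage("correlogram"):
        d = patristic_distances(tree).submatrix(species)
        bundle["correlograms"] = {
            t: _correlogram(
                traits[t].to_numpy(float), d, n_classes=n_classes,
                n_perm=n_perm, seed=rng_corr, trait_name=t,
            )
            for t in TRAITS
        }

    with _stage("phyl_anova_mht"):
        bundle["phyl_anova_MHT"] = pg.phyl_anova(
            traits["MHT"].to_numpy(float), traits["province"], tree,
            n_sim=n_sim, seed=rng_anova, species=species,
        )

    with _stage("pgls_ancova"):
        ancova = {}
        for limit in ("LL50", "UL50"):
            model = pg.PGLS.from_dataframe(
                traits, response=limit, factors=["province"], covariates=["MHT"],
                interactions=[("province", "MHT")], tree=tree,
            )
            fit = model.fit_ou()
            ancova[limit] = {
                "fit": fit,
                "alpha": fit.alpha,
                "alpha_at_boundary": fit.alpha_at_boundary,
                "sequential": fit.anova("sequential"),
                "marginal": fit.anova("marginal"),
            }
        bundle["ancova"] = ancova

    with _stage("posthoc"):
        posthoc = {
            "MHT": pg.posthoc_holm(
                traits["MHT"].to_numpy(float), traits["province"], tree,
                n_sim=n_sim, seed=rng_posthoc, species=species,
            )
        }
        for limit in ("LL50", "UL50"):
            posthoc[limit] = pg.posthoc_holm(
                traits[limit].to_numpy(float), traits["province"], tree,
                n_sim=n_sim, seed=rng_posthoc, species=species,
                covariate=traits["MHT"].to_numpy(float),
            )
        bundle["posthoc"] = posthoc

    bundle["provenance"] = _provenance(seed, n_perm, n_sim, n_classes, traits)
    if out_dir is not None:
        _write_bundle(bundle, out_dir)
    return bundle


def _provenance(seed, n_perm, n_sim, n_classes, traits) -> dict:
    import dendropy
    import scipy

    from . import __version__

    config = {
        "seed": seed, "n_perm": n_perm, "n_sim": n_sim, "n_classes": n_classes,
        "n_species": len(traits),
    }
    digest = hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()[:16]
    return {
        "phylotherm": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "dendropy": dendropy.__version__,
        "config": config,
        "config_hash": digest,
    }


def render_report(bundle: dict) -> str:
    """Markdown report body (no timestamps, so regeneration is byte-stable)."""
    lines = ["# Comparative thermal-tolerance analysis", ""]
    prov = bundle["provenance"]
    lines += [
        f"seed {prov['config']['seed']}, config hash {prov['config_hash']}, "
        f"phylotherm {prov['phylotherm']} (numpy {prov['numpy']}, scipy {prov['scipy']})",
        "",
        "> Tree-dependent statistics below (Moran's I, alpha, ANCOVA F) were",
        "> computed on a taxonomy-informed SURROGATE tree with arbitrary branch",
        "> lengths and are not comparable to values from the study's",
        "> unpublished molecular phylogeny.",
        "",
        "## Province summaries",
        "",
        bundle["province_summary"].summary(),
        "",
        "Note: the Magellanic LL50 species mean is exactly -0.15 deg C; it is",
        "displayed as -0.2 under the half-away-from-zero display convention.",
        "",
        "## Phylogenetic correlograms",
        "",
    ]
    for t, res in bundle["correlograms"].items():
        lines += [res.summary(), ""]
    lines += ["## Phylogenetic ANOVA: MHT ~ province", "",
              bundle["phyl_anova_MHT"].summary(), ""]
    for limit, parts in bundle["ancova"].items():
        fit = parts["fit"]
        lines += [
            f"## PGLS ANCOVA (OU): {limit} ~ province + MHT + province:MHT",
            "",
            f"alpha = {fit.alpha:.4g}"
            + (" (boundary)" if parts["alpha_at_boundary"] else ""),
            f"loglik = {fit.llf:.4f}",
            "",
            parts["sequential"].summary(),
            "",
            parts["marginal"].summary(),
            "",
        ]
    lines += ["## Post hoc comparisons (BM-simulation p, Holm-adjusted)", ""]
    for t, res in bundle["posthoc"].items():
        lines += [f"### {t}", "", res.summary(), ""]
    return "\n".join(lines)


def _write_bundle(bundle: dict, out_dir: str) -> None:
    import os

    os.makedirs(out_dir, exist_ok=True)
    with open(os.path.join(out_dir, "report.md"), "w") as fh:
        fh.write(render_report(bundle))
    bundle["province_summary"].to_frame().to_csv(
        os.path.join(out_dir, "province_summary.tsv"), sep="\t"
    )
    for t, res in bundle["correlograms"].items():
        res.to_frame().to_csv(os.path.join(out_dir, f"correlogram_{t}.tsv"), sep="\t", index=False)
    bundle["phyl_anova_MHT"].to_frame().to_csv(
        os.path.join(out_dir, "phyl_anova_MHT.tsv"), sep="\t"
    )
    for limit, parts in bundle["ancova"].items():
        parts["sequential"].to_frame().to_csv(
            os.path.join(out_dir, f"ancova_sequential_{limit}.tsv"), sep="\t"
        )
        parts["marginal"].to_frame().to_csv(
            os.path.join(out_dir, f"ancova_marginal_{limit}.tsv"), sep="\t"
        )
        parts["fit"].alpha_profile.to_csv(
            os.path.join(out_dir, f"alpha_profile_{limit}.csv"), index=False
        )
    for t, res in bundle["posthoc"].items():
        res.to_frame().to_csv(os.path.join(out_dir, f"posthoc_{t}.tsv"), sep="\t", index=False)
    with open(os.path.join(out_dir, "provenance.json"), "w") as fh:
        json.dump(bundle["provenance"], fh, indent=2, sort_keys=True)
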