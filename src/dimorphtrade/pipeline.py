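"""End-to-end analysis pipeline with seeded stages and JSON/CSV outputs.

Stage order mirrors the study design: trophic axis -> common size
correction -> phenotype-environment correlation (permutation + PGLS) ->
species-specific size correction -> per-species dimorphism -> grand means
per breeding mode -> permutation and phylogenetic ANOVA on absolute
dimorphism -> Davies test + segmented regression within uni-parental
mouthbrooders -> breakpoint grouping + phylogenetic ANOVA. Every stage
draws from its own child stream of one global seed, so runs are
reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from dimorphtrade import (
    breakpoint as bkpt,
    dimorphism as dim,
    io as dio,
    phylo,
    resampling,
    simulate as sim,
    sizecorr,
    trophic,
)

log = logging.getLogger("dimorphtrade")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage tag."""


@dataclass
class PipelineConfig:
    """Run configuration; exactly one of `input` / `simulate` must be set."""

    seed: int = 0
    input: dict | None = None           # {"specimens": path, "tree": path}
    simulate: dict | None = None        # SimConfig fields
    resampling: dict = field(default_factory=lambda: {"n_perm": 10000, "n_boot": 10000})
    phylo: dict = field(default_factory=lambda: {"n_sim": 1000, "lambda_mode": "ML"})
    breakpoint: dict = field(default_factory=lambda: {"n_candidates": 10, "psi0": None})
    size_correction: dict = field(default_factory=lambda: {"shift": "auto"})

    def __post_init__(self):
        if (self.input is None) == (self.simulate is None):
            raise ValueError("exactly one of 'input' and 'simulate' must be given")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        base = cls(seed=raw.get("seed", 0), input=raw.get("input"),
                   simulate=raw.get("simulate"))
        for key in ("resampling", "phylo", "breakpoint", "size_correction"):
            getattr(base, key).update(raw.get(key) or {})
        return base


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not serializable: {type(o)}")


def _write_json(obj, path):
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
        return wrapped
    return deco


@_stage("load")
def _load_data(config: PipelineConfig, out: Path, rng: np.random.Generator):
    if config.simulate is not None:
        sim_kwargs = dict(config.simulate)
        sim_kwargs.setdefault("seed", config.seed)
        cfg = sim.SimConfig(**sim_kwargs)
        raw_table, tree, truth = sim.generate_study(cfg)
        raw_table.to_csv(out / "specimens.csv", index=False)
        tree.write(out / "tree.nwk")
        truth.to_json(out / "truth.json")
        buf = _io.StringIO(raw_table.to_csv(index=False))
        table, report = dio.read_specimen_table(buf)
    else:
        table, report = dio.read_specimen_table(config.input["specimens"])
        tree = dio.read_newick(config.input["tree"])
    log.info("loaded %d specimens, %d species, %d tree tips",
             len(table), table["species"].nunique(), len(tree.tip_labels))
    return table, tree, report


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Run every stage, write the result bundle under `out_dir`, return it."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    streams = np.random.SeedSequence(config.seed).spawn(8)
    rngs = [np.random.default_rng(s) for s in streams]
    n_perm = int(config.resampling.get("n_perm", 10000))
    n_boot = int(config.resampling.get("n_boot", 10000))
    bundle: dict = {"seed": config.seed}

    table, tree, load_report = _load_data(config, out, rngs[0])
    bundle["n_specimens"] = len(table)
    bundle["load_report"] = {"n_read": load_report.n_read,
                             "n_accepted": load_report.n_accepted,
                             "rejected": load_report.rejected}

    # --- trophic axis -----------------------------------------------------
    try:
        axis = trophic.compute_trophic_axis(table["d13C"].to_numpy(),
                                            table["d15N"].to_numpy())
        pc1, no_iso = trophic.species_pc1_scores(axis, table)
    except Exception as exc:
        raise PipelineError(f"[trophic_axis] {exc}") from exc
    _write_json({"loading_d13C": axis.loading_d13C, "loading_d15N": axis.loading_d15N,
                 "pct_variance_pc1": axis.pct_variance_pc1,
                 "species_without_isotopes": no_iso}, out / "axis.json")
    pc1_df = pc1.rename("trophic_pc1").reset_index()
    counts = table.groupby("species", sort=False).size()
    pc1_df["n"] = pc1_df["species"].map(counts)
    pc1_df.to_csv(out / "species_pc1.csv", index=False)
    bundle["axis"] = {"loading_d13C": axis.loading_d13C,
                      "loading_d15N": axis.loading_d15N,
                      "pct_variance_pc1": axis.pct_variance_pc1}

    # --- common size correction ------------------------------------------
    try:
        sc_common, fit = sizecorr.common_size_correct(
            table, shift=config.size_correction.get("shift", "auto"))
    except Exception as exc:
        raise PipelineError(f"[size_correction] {exc}") from exc
    sc_common.to_csv(out / "sizecorr.csv", index=False)
    species_mean_sc = sc_common.groupby("species", sort=False)["raker_sc"].mean()
    bundle["common_fit"] = dataclasses.asdict(fit)

    # --- phenotype-environment correlation -------------------------------
    common_species = [sp for sp in pc1.index if sp in species_mean_sc.index]
    x = pc1.loc[common_species].to_numpy()
    y = species_mean_sc.loc[common_species].to_numpy()
    try:
        perm = resampling.perm_corr_test(x, y, n_perm=n_perm, seed=rngs[1])
        pruned, prune_report = dio.match_and_prune(tree, common_species)
        tip_order = [sp for sp in common_species
                     if sp not in set(prune_report.missing_from_tree)]
        label_of = {dio.normalize_species(l): l for l in pruned.tip_labels}
        tree_labels = [label_of[dio.normalize_species(sp)] for sp in tip_order]
        cov = phylo.bm_covariance(pruned).sub(tree_labels)
        X = np.column_stack([np.ones(len(tip_order)), pc1.loc[tip_order].to_numpy()])
        pg = phylo.pgls_fit(species_mean_sc.loc[tip_order].to_numpy(), X, cov,
                            lambda_mode=config.phylo.get("lambda_mode", "ML"),
                            lambda_fixed=config.phylo.get("lambda_fixed"))
    except Exception as exc:
        raise PipelineError(f"[phenotype_env] {exc}") from exc
    r_obs = perm.observed_stat
    phenotype_env = {
        "n_species": len(common_species),
        "pearson_r": r_obs,
        "r_squared_ols": r_obs**2,
        "p_permutation": perm.p_value,
        "n_perm": perm.n_perm,
        "pgls": {"r_squared": pg.r_squared, "lambda": pg.lambda_,
                 "p_slope": pg.p_value_slope,
                 "coefficients": pg.coefficients.tolist(),
                 "lambda_at_bound": pg.lambda_at_bound,
                 "n_species": len(tip_order),
                 "species_dropped_from_tree": prune_report.missing_from_tree},
    }
    _write_json(phenotype_env, out / "phenotype_env.json")
    bundle["phenotype_env"] = phenotype_env

    # --- dimorphism -------------------------------------------------------
    sexed = table[table["sex"].isin(("female", "male"))]
    try:
        sc_sp, sc_excluded = sizecorr.per_species_size_correct(sexed)
        records, dim_excluded = dim.dimorphism_table(sc_sp, n_perm=n_perm,
                                                     n_boot=n_boot, seed=rngs[2])
        grand, grand_excluded = dim.grand_means_by_mode(records, n_perm=n_perm,
                                                        n_boot=n_boot, seed=rngs[3])
    except Exception as exc:
        raise PipelineError(f"[dimorphism] {exc}") from exc
    records.to_csv(out / "dimorphism.csv", index=False)
    bundle["dimorphism"] = {"n_tested_species": len(records),
                            "excluded": sc_excluded + dim_excluded}
    bundle["grand_means"] = grand.to_dict(orient="records")

    # --- ANOVA across breeding modes on |F - M| ---------------------------
    anova_out: dict = {"grand_means": bundle["grand_means"],
                       "excluded_modes": grand_excluded}
    try:
        modes_present = records["breeding_mode"].value_counts()
        usable = records[records["breeding_mode"].isin(
            modes_present.index[modes_present >= 2])]
        if usable["breeding_mode"].nunique() >= 2:
            omnibus, pairs = resampling.perm_anova(
                usable["abs_diff"].to_numpy(), usable["breeding_mode"].to_numpy(),
                n_perm=n_perm, seed=rngs[4])
            anova_out["perm_anova"] = {
                "F": omnibus.observed_stat, "p": omnibus.p_value,
                "n_perm": omnibus.n_perm,
                "pairwise": {f"{a}|{b}": res.p_value for (a, b), res in pairs.items()},
            }
            ptree, prep = dio.match_and_prune(tree, list(usable["species"]))
            in_tree = usable[~usable["species"].isin(set(prep.missing_from_tree))]
            label_of = {dio.normalize_species(l): l for l in ptree.tip_labels}
            order = [label_of[dio.normalize_species(sp)] for sp in in_tree["species"]]
            pmodes = in_tree["breeding_mode"].value_counts()
            if (in_tree["breeding_mode"].nunique() >= 2 and (pmodes >= 2).all()):
                pa = phylo.phyl_anova(
                    in_tree["abs_diff"].to_numpy(), in_tree["breeding_mode"].to_numpy(),
                    phylo.bm_covariance(ptree).sub(order),
                    n_sim=int(config.phylo.get("n_sim", 1000)), seed=rngs[5])
                anova_out["phyl_anova"] = {
                    "F": pa.F_obs, "p": pa.p_phylo, "n_sim": pa.n_sim,
                    "pairwise_holm": {f"{a}|{b}": p for (a, b), p in pa.pairwise_p.items()},
                }
            else:
                anova_out["phyl_anova"] = {"skipped": "a mode has <2 species in the tree"}
        else:
            anova_out["perm_anova"] = {"skipped": "fewer than 2 modes with >=2 species"}
    except Exception as exc:
        raise PipelineError(f"[anova] {exc}") from exc
    _write_json(anova_out, out / "anova.json")
    bundle["anova"] = anova_out

    # --- breakpoint within uni-parental mouthbrooders ---------------------
    uni = records[records["breeding_mode"] == "uniparental"]
    seg_out: dict = {}
    groups_out: dict = {}
    try:
        if len(uni) >= 6:
            xs = pc1.loc[uni["species"]].to_numpy()
            ys = uni["abs_diff"].to_numpy()
            dv = bkpt.davies_test(xs, ys,
                                  n_candidates=int(config.breakpoint.get("n_candidates", 10)))
            fit = bkpt.segmented_fit(xs, ys, psi0=config.breakpoint.get("psi0"))
            seg_out = {
                "davies": {"p": dv.p_value, "best_candidate": dv.best_candidate,
                           "n_candidates": dv.n_candidates},
                "psi": fit.psi, "psi_se": fit.psi_se,
                "slope_left": fit.slope_left, "slope_right": fit.slope_right,
                "intercept": fit.intercept, "converged": fit.converged,
                "n_iter": fit.n_iter, "n_species": len(uni),
            }
            assign = bkpt.assign_groups_by_breakpoint(
                pd.Series(xs, index=uni["species"].to_numpy()), fit.psi)
            groups_out = {"psi": fit.psi, "assignment": assign}
            glabels = np.array([assign[sp] for sp in uni["species"]])
            sizes = pd.Series(glabels).value_counts()
            if len(sizes) == 2 and (sizes >= 2).all():
                ptree, prep = dio.match_and_prune(tree, list(uni["species"]))
                in_tree = uni[~uni["species"].isin(set(prep.missing_from_tree))]
                label_of = {dio.normalize_species(l): l for l in ptree.tip_labels}
                order = [label_of[dio.normalize_species(sp)] for sp in in_tree["species"]]
                gl = np.array([assign[sp] for sp in in_tree["species"]])
                if len(np.unique(gl)) == 2 and min(np.bincount(pd.factorize(gl)[0])) >= 2:
                    pa = phylo.phyl_anova(
                        in_tree["abs_diff"].to_numpy(), gl,
                        phylo.bm_covariance(ptree).sub(order),
                        n_sim=int(config.phylo.get("n_sim", 1000)), seed=rngs[6])
                    groups_out["phyl_anova"] = {"F": pa.F_obs, "p": pa.p_phylo,
                                                "n_sim": pa.n_sim}
                else:
                    groups_out["phyl_anova"] = {"skipped": "a group has <2 species in tree"}
            else:
                groups_out["phyl_anova"] = {"skipped": "a breakpoint group has <2 species"}
        else:
            seg_out = {"skipped": f"only {len(uni)} uni-parental species (need >= 6)"}
            groups_out = {"skipped": seg_out["skipped"]}
    except Exception as exc:
        raise PipelineError(f"[breakpoint] {exc}") from exc
    _write_json(seg_out, out / "segmented.json")
    _write_json(groups_out, out / "groups.json")
    bundle["segmented"] = seg_out
    bundle["groups"] = groups_out

    with open(out / "run_log.txt", "w") as fh:
        fh.write(f"seed: {config.seed}\n")
        fh.write(f"n_perm: {n_perm}, n_boot: {n_boot}, "
                 f"phylo n_sim: {config.phylo.get('n_sim', 1000)}\n")
        fh.write("stages: trophic_axis, size_correction, phenotype_env, dimorphism, "
                 "grand_means, anova, breakpoint, groups\n")
        for idx, reason in bundle["load_report"]["rejected"]:
            fh.write(f"rejected specimen row {idx}: {reason}\n")
    _write_json(bundle, out / "bundle.json")
    return bundle


def report(bundle: dict) -> str:
    """Human-readable markdown summary of a result bundle."""
    lines = ["# dimorphtrade run summary", ""]
    warn = []
    ax = bundle.get("axis")
    if ax:
        lines += ["## Trophic axis",
                  f"PC1 explains {ax['pct_variance_pc1']:.1f}% of isotope variance; "
                  f"loadings d13C = {ax['loading_d13C']:.2f}, "
                  f"d15N = {ax['loading_d15N']:.2f}.", ""]
    else:
        warn.append("trophic axis missing")
    cf = bundle.get("common_fit")
    if cf:
        lines += ["## Common size correction",
                  f"raker ~ SL: slope {cf['slope']:.4f} mm/mm, "
                  f"R^2 = {cf['r_squared']:.2f} (n = {cf['n']}).", ""]
    pe = bundle.get("phenotype_env")
    if pe:
        lines += ["## Phenotype-environment correlation",
                  f"Pearson r = {pe['pearson_r']:.2f} over {pe['n_species']} species "
                  f"(permutation p = {pe['p_permutation']:.4g}).",
                  f"PGLS: R^2 = {pe['pgls']['r_squared']:.2f}, "
                  f"lambda = {pe['pgls']['lambda']:.2f}, "
                  f"slope p = {pe['pgls']['p_slope']:.4g}.", ""]
    gm = bundle.get("grand_means")
    if gm:
        lines.append("## Grand means per breeding mode")
        for row in gm:
            lines.append(
                f"- {row['breeding_mode']}: mean F-M = {row['mean_signed_diff']:.3f} mm "
                f"[{row['signed_ci_lower']:.3f}, {row['signed_ci_upper']:.3f}], "
                f"p(mean=0) = {row['p_mean_zero']:.4g}; "
                f"mean |F-M| = {row['mean_abs_diff']:.3f} mm (n = {row['n_species']})")
        lines.append("")
    an = bundle.get("anova", {})
    if "perm_anova" in an and "F" in an.get("perm_anova", {}):
        pa = an["perm_anova"]
        lines += ["## Extent of dimorphism across breeding modes",
                  f"Permutation ANOVA: F = {pa['F']:.2f}, p = {pa['p']:.4g}."]
        if "phyl_anova" in an and "F" in an["phyl_anova"]:
            ph = an["phyl_anova"]
            lines.append(f"Phylogenetic ANOVA: F = {ph['F']:.2f}, p = {ph['p']:.4g}.")
        elif "phyl_anova" in an:
            warn.append(f"phylogenetic ANOVA skipped: {an['phyl_anova'].get('skipped')}")
        lines.append("")
    seg = bundle.get("segmented", {})
    if "psi" in seg:
        lines += ["## Breakpoint in uni-parental mouthbrooders",
                  f"Davies test p = {seg['davies']['p']:.4g}; segmented breakpoint "
                  f"psi = {seg['psi']:.3f} (SE {seg['psi_se']:.3f}), slopes "
                  f"{seg['slope_left']:.3f} -> {seg['slope_right']:.3f}.", ""]
        gr = bundle.get("groups", {})
        if "phyl_anova" in gr and "F" in gr.get("phyl_anova", {}):
            g = gr["phyl_anova"]
            lines.append(f"Breakpoint groups (phylogenetic ANOVA): F = {g['F']:.2f}, "
                         f"p = {g['p']:.4g}.")
            lines.append("")
        elif "phyl_anova" in gr:
            warn.append(f"breakpoint-group ANOVA skipped: {gr['phyl_anova'].get('skipped')}")
    elif "skipped" in seg:
        lines += ["## Breakpoint in uni-parental mouthbrooders",
                  f"skipped: {seg['skipped']}", ""]
    if warn:
        lines.append("## Warnings")
        lines += [f"- {w}" for w in warn]
        lines.append("")
    return "\n".join(lines)
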