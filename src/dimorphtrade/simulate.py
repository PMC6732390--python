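"""Synthetic study generator: Yule tree, BM trophic trait, specimen table.

The generator emulates the shape of a comparative study of Lake Tanganyika
cichlids: ~65 species with ~10 specimens each, three breeding modes
(uni-parental mouthbrooding, bi-parental mouthbrooding, substrate
guarding), a species-level trophic score evolving by Brownian motion on a
Yule tree, specimen gill raker length scaling linearly with standard
length and with the trophic score, and a sex effect confined to
uni-parental species whose magnitude follows a hinge in the trophic score:
zero below the breakpoint ``psi*`` and growing linearly above it, with a
random per-species direction. Isotope pairs are back-constructed so that
the downstream standardized PCA recovers the simulated trophic axis on the
same scale as the ground truth stored in the TruthRecord.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import dendropy
import numpy as np
import pandas as pd

from dimorphtrade.io import Phylogeny


@dataclass
class SimConfig:
    """Generative parameters; defaults state the study-shaped world."""

    n_species: int = 65
    n_per_species: int = 10
    birth_rate: float = 1.0                 # Yule speciation rate, per unit time
    bm_sigma2_trophic: float = 1.0          # BM rate of the latent trophic trait
    raker_intercept: float = 0.2            # mm
    raker_slope_on_sl: float = 0.01         # mm per mm SL
    raker_slope_on_trophic: float = 0.15    # mm per PC1 unit
    true_breakpoint: float = 0.34           # psi*, PC1 units
    dimorphism_slope: float = 0.4           # mm per PC1 unit above psi*
    residual_sd: float = 0.15               # mm, specimen-level
    sl_log_mean: float = float(np.log(90.0))  # log mm
    sl_log_sd: float = 0.3
    breeding_mode_probs: tuple = (0.45, 0.20, 0.35)  # uni, bi, non
    pc2_sd: float = 0.5418                  # nuisance isotope axis; gives ~77% PC1 var
    raker_measurement_sd: float = 0.02      # mm jitter across the 3 measured rakers
    d13c_mean: float = -18.0                # per mil
    d13c_sd: float = 2.5
    d15n_mean: float = 7.5
    d15n_sd: float = 1.5
    seed: int = 0

    def __post_init__(self):
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if abs(sum(self.breeding_mode_probs) - 1.0) > 1e-9:
            raise ValueError("breeding_mode_probs must sum to 1")
        for name in ("birth_rate", "bm_sigma2_trophic", "residual_sd", "sl_log_sd",
                     "pc2_sd", "raker_measurement_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


MODES = ("uniparental", "biparental", "nonmouthbrooding")


def _rng(seed):
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_yule_tree(n_species: int, birth_rate: float = 1.0, seed=None) -> Phylogeny:
    """Pure-birth tree with `n_species` tips and exponential waiting times.

    The process starts from a single stem lineage at time 0, so the
    expected lineage count at time t is e^(birth_rate * t). After the last
    split the tree is extended by one further Exp(n * rate) waiting time so
    every tip has positive terminal branch length; the tree is ultrametric
    and the stem is kept as the root edge.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = _rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    t = 0.0
    active = [(tree.seed_node, 0.0)]  # (node, branch start time)
    while len(active) < n_species:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        i = int(rng.integers(k))
        node, t0 = active.pop(i)
        node.edge.length = t - t0
        c1, c2 = dendropy.Node(), dendropy.Node()
        node.add_child(c1)
        node.add_child(c2)
        active.append((c1, t))
        active.append((c2, t))
    t_end = t + rng.exponential(1.0 / (birth_rate * n_species))
    width = len(str(n_species))
    for idx, (node, t0) in enumerate(active):
        node.edge.length = t_end - t0
        node.taxon = tns.new_taxon(label=f"sp{idx + 1:0{width}d}")
    return Phylogeny(tree)


def simulate_bm_trait(tree: Phylogeny, sigma2: float, root_value: float = 0.0,
                      seed=None) -> dict:
    """Brownian motion on the tree: tip values ~ MVN(root, sigma2 * C).

    Simulated by accumulating independent Normal(0, sigma2 * branch length)
    increments down every edge (root stem included if present).
    """
    if sigma2 < 0:
        raise ValueError("sigma2 must be >= 0")
    rng = _rng(seed)
    out = {}

    def walk(node, value):
        for ch in node.child_nodes():
            v = value + rng.normal(0.0, np.sqrt(sigma2 * ch.edge.length))
            if ch.is_leaf():
                out[ch.taxon.label] = float(v)
            else:
                walk(ch, v)

    seed_node = tree.tree.seed_node
    stem = seed_node.edge.length or 0.0
    start = root_value + (rng.normal(0.0, np.sqrt(sigma2 * stem)) if stem else 0.0)
    if seed_node.is_leaf():
        out[seed_node.taxon.label] = float(start)
    else:
        walk(seed_node, start)
    return out


@dataclass
class TruthRecord:
    """Ground truth stored next to every generated dataset."""

    psi_star: float
    dimorphism_slope: float
    raker_intercept: float
    raker_slope_on_sl: float
    raker_slope_on_trophic: float
    residual_sd: float
    species: dict = field(default_factory=dict)
    # per species: breeding_mode, pc1_true, dimorphism_sign,
    # expected_signed_diff (female - male, mm)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)


def generate_study(config: SimConfig):
    """Generate (specimen table, tree, truth) under `config`.

    The latent species trophic trait is standardized across species and
    scaled by sqrt(2 / (1 + pc2_sd^2)) - the analytic PC1 score scale of the
    back-constructed isotopes - so the hinge breakpoint ``true_breakpoint``
    and the trophic slope live on the same scale the pipeline's PCA
    recovers. Each specimen carries three raker measurements (small
    measurement jitter around the specimen value), a lognormal standard
    length, and isotopes built from the species score plus an independent
    nuisance axis. Fixed seed means byte-identical output.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_yule_tree(cfg.n_species, cfg.birth_rate, rng)
    species = tree.tip_labels
    raw = simulate_bm_trait(tree, cfg.bm_sigma2_trophic, 0.0, rng)
    vals = np.array([raw[sp] for sp in species])
    sd = vals.std(ddof=1)
    s_std = (vals - vals.mean()) / (sd if sd > 0 else 1.0)
    scale = np.sqrt(2.0 / (1.0 + cfg.pc2_sd**2))
    pc1_true = s_std * scale

    modes = rng.choice(MODES, size=cfg.n_species, p=list(cfg.breeding_mode_probs))
    signs = rng.choice([-1.0, 1.0], size=cfg.n_species)

    rows = []
    truth_species = {}
    for i, sp in enumerate(species):
        mode = str(modes[i])
        hinge = max(0.0, pc1_true[i] - cfg.true_breakpoint)
        effect = signs[i] * cfg.dimorphism_slope * hinge if mode == "uniparental" else 0.0
        truth_species[sp] = {
            "breeding_mode": mode,
            "pc1_true": float(pc1_true[i]),
            "dimorphism_sign": float(signs[i]) if mode == "uniparental" else 0.0,
            "expected_signed_diff": float(effect),
        }
        n = cfg.n_per_species
        sexes = np.array(["female", "male"] * ((n + 1) // 2))[:n]
        sl = rng.lognormal(cfg.sl_log_mean, cfg.sl_log_sd, size=n)
        noise = rng.normal(0.0, cfg.residual_sd, size=n)
        pc2 = rng.normal(0.0, cfg.pc2_sd, size=n)
        jitter = rng.normal(0.0, cfg.raker_measurement_sd, size=(n, 3))
        sex_shift = np.where(sexes == "female", 0.5 * effect, -0.5 * effect)
        raker = (cfg.raker_intercept + cfg.raker_slope_on_sl * sl
                 + cfg.raker_slope_on_trophic * pc1_true[i] + sex_shift + noise)
        raker = np.maximum(raker, 0.01)
        # measurements are lengths: floor each jittered raker at 5 microns
        measured = np.maximum(raker[:, None] + jitter, 0.005)
        z13 = (-s_std[i] + pc2) / np.sqrt(2.0)
        z15 = (s_std[i] + pc2) / np.sqrt(2.0)
        for j in range(n):
            rows.append({
                "specimen_id": f"{sp}_{j + 1:02d}",
                "species": sp,
                "sex": sexes[j],
                "standard_length": round(float(sl[j]), 6),
                "raker_1": round(float(measured[j, 0]), 6),
                "raker_2": round(float(measured[j, 1]), 6),
                "raker_3": round(float(measured[j, 2]), 6),
                "d13C": round(float(cfg.d13c_mean + cfg.d13c_sd * z13[j]), 6),
                "d15N": round(float(cfg.d15n_mean + cfg.d15n_sd * z15[j]), 6),
                "breeding_mode": mode,
            })
    table = pd.DataFrame(rows)
    truth = TruthRecord(
        psi_star=cfg.true_breakpoint,
        dimorphism_slope=cfg.dimorphism_slope,
        raker_intercept=cfg.raker_intercept,
        raker_slope_on_sl=cfg.raker_slope_on_sl,
        raker_slope_on_trophic=cfg.raker_slope_on_trophic,
        residual_sd=cfg.residual_sd,
        species=truth_species,
    )
    return table, tree, truth
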