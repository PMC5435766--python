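"""Simulation of biparental DH panels, immortalized-F2 crossing designs and
multi-environment phenotypes with known ground truth.

The generative model mirrors the analysis models downstream: genetic values
are sums of additive, dominance and digenic-epistatic marker effects; each
environment redraws every effect vector around its truth value (tunable
genotype-by-environment interaction per effect class), adds an environment
main effect and plot-level residual noise.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    CrossingDesign,
    DataError,
    GeneticMap,
    GROUP_HYBRID,
    GROUP_INBRED,
    MarkerMatrix,
    PhenotypeTable,
    STAGE_PLOT,
    default_map,
)

EPI_TYPES = ("AA", "AD", "DA", "DD")


def stream(seed: int, name: str) -> np.random.Generator:
    """Named child RNG stream: one master seed, stable per-stage substreams."""
    digest = hashlib.sha256(name.encode()).digest()[:8]
    key = int.from_bytes(digest, "little")
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class SimTruth:
    """Generative parameters; ``seed`` fully determines every simulated value.

    ``epistatic_pairs`` entries are (marker_index_1, marker_index_2, type,
    effect) with type in {AA, AD, DA, DD}; ``gxe_sd`` maps effect class
    ("additive", "dominance", "epistasis") to the per-environment redraw
    scale expressed as a multiple of that class's effect RMS.
    """

    qtl_positions: list
    additive_effects: list
    dominance_effects: list
    epistatic_pairs: list
    env_effects: list
    gxe_sd: dict
    residual_sd: float
    seed: int

    def __post_init__(self) -> None:
        nq = len(self.qtl_positions)
        if len(self.additive_effects) != nq or len(self.dominance_effects) != nq:
            raise ConfigurationError("effect vectors must align with qtl_positions")
        for pair in self.epistatic_pairs:
            if len(pair) != 4 or pair[2] not in EPI_TYPES:
                raise ConfigurationError(f"bad epistatic pair {pair!r}")
        for cls in ("additive", "dominance", "epistasis"):
            self.gxe_sd.setdefault(cls, 0.0)

    def validate_indices(self, n_markers: int) -> None:
        idx = list(self.qtl_positions) + [p[0] for p in self.epistatic_pairs] + [
            p[1] for p in self.epistatic_pairs
        ]
        if idx and (min(idx) < 0 or max(idx) >= n_markers):
            raise ConfigurationError("QTL index out of range for the marker panel")

    def to_json(self, path: str | Path) -> None:
        d = asdict(self)
        d["epistatic_pairs"] = [list(p) for p in self.epistatic_pairs]
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["epistatic_pairs"] = [tuple(p) for p in d["epistatic_pairs"]]
        return cls(**d)


def _class_scale(effects: np.ndarray) -> float:
    effects = np.asarray(effects, dtype=float)
    if effects.size == 0:
        return 0.0
    return float(np.sqrt(np.mean(effects**2)))


def genetic_values(
    codes: np.ndarray,
    truth: SimTruth,
    additive: np.ndarray | None = None,
    dominance: np.ndarray | None = None,
    epistatic: np.ndarray | None = None,
) -> np.ndarray:
    """Genetic value of each individual given (possibly env-redrawn) effects."""
    a = np.asarray(truth.additive_effects if additive is None else additive, dtype=float)
    d = np.asarray(truth.dominance_effects if dominance is None else dominance, dtype=float)
    e = (
        np.array([p[3] for p in truth.epistatic_pairs], dtype=float)
        if epistatic is None
        else np.asarray(epistatic, dtype=float)
    )
    g = np.zeros(codes.shape[0])
    if len(truth.qtl_positions):
        x = codes[:, truth.qtl_positions]
        z = (x == 0).astype(float)
        g += x @ a + z @ d
    for k, (i, j, typ, _) in enumerate(truth.epistatic_pairs):
        xi, xj = codes[:, i], codes[:, j]
        zi, zj = (xi == 0).astype(float), (xj == 0).astype(float)
        col = {"AA": xi * xj, "AD": xi * zj, "DA": zi * xj, "DD": zi * zj}[typ]
        g += e[k] * col
    return g


# ---------------------------------------------------------------------------
# DH population
# ---------------------------------------------------------------------------


def haldane_r(d_cm: np.ndarray) -> np.ndarray:
    """Haldane recombination fraction for a map distance in centimorgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_cm, dtype=float) / 100.0))


def simulate_gametes(gmap: GeneticMap, n: int, rng: np.random.Generator) -> np.ndarray:
    """F1 gametes as +-1 parental-origin indicators, Haldane meiosis
    (no crossover interference)."""
    out = np.empty((n, gmap.n_markers))
    chrom = gmap.chromosome
    for c in pd.unique(chrom):
        idx = np.where(chrom == c)[0]
        pos = gmap.position_cm[idx]
        m = len(idx)
        alleles = np.empty((n, m))
        alleles[:, 0] = rng.choice([-1.0, 1.0], size=n)
        if m > 1:
            r = haldane_r(np.diff(pos))
            flips = rng.random((n, m - 1)) < r[None, :]
            sign = np.where(flips, -1.0, 1.0)
            alleles[:, 1:] = alleles[:, [0]] * np.cumprod(sign, axis=1)
        out[:, idx] = alleles
    return out


def simulate_dh_population(
    gmap: GeneticMap, n_lines: int, seed: int, id_prefix: str = "DH"
) -> MarkerMatrix:
    """Doubled-haploid lines from a biparental F1: one meiosis per line,
    the gamete genome doubled, so every locus is homozygous (+-1)."""
    if gmap is None or gmap.n_markers == 0:
        raise ConfigurationError("empty genetic map")
    if n_lines < 2:
        raise ConfigurationError("need at least 2 DH lines")
    rng = stream(seed, "dh")
    codes = simulate_gametes(gmap, n_lines, rng)
    ids = np.array([f"{id_prefix}{i + 1:04d}" for i in range(n_lines)], dtype=object)
    group = np.full(n_lines, GROUP_INBRED, dtype=object)
    return MarkerMatrix(codes, gmap, ids, group)


# ---------------------------------------------------------------------------
# Crossing design
# ---------------------------------------------------------------------------


def make_crossing_design(
    parents: int | Sequence, n_crosses: int, seed: int
) -> CrossingDesign:
    """Random unordered pairs without replacement; per-parent usage capped at
    ceil(2*n_crosses/n_parents)+1 so every line serves as a parent."""
    if isinstance(parents, (int, np.integer)):
        ids = list(range(1, int(parents) + 1))
    else:
        ids = list(parents)
    n_par = len(ids)
    max_pairs = n_par * (n_par - 1) // 2
    if n_crosses > max_pairs:
        raise ConfigurationError(f"{n_crosses} crosses infeasible with {n_par} parents")
    if n_crosses < 1:
        raise ConfigurationError("need at least one cross")
    if n_crosses == max_pairs:
        crosses = [(ids[i], ids[j]) for i in range(n_par) for j in range(i + 1, n_par)]
        return CrossingDesign(tuple(crosses))
    rng = stream(seed, "crosses")
    cap = math.ceil(2 * n_crosses / n_par) + 1
    usage = {p: 0 for p in ids}
    chosen: list = []
    seen: set = set()
    # pass 1: ensure coverage by pairing a shuffled ring
    order = list(ids)
    rng.shuffle(order)
    for k in range(0, n_par - 1, 2):
        if len(chosen) >= n_crosses:
            break
        p, q = order[k], order[k + 1]
        chosen.append((p, q))
        seen.add(frozenset((p, q)))
        usage[p] += 1
        usage[q] += 1
    attempts = 0
    while len(chosen) < n_crosses:
        attempts += 1
        if attempts > 200 * n_crosses:
            raise ConfigurationError("could not place crosses under the usage cap")
        p, q = rng.choice(n_par, size=2, replace=False)
        p, q = ids[int(p)], ids[int(q)]
        key = frozenset((p, q))
        if key in seen or usage[p] >= cap or usage[q] >= cap:
            continue
        chosen.append((p, q))
        seen.add(key)
        usage[p] += 1
        usage[q] += 1
    return CrossingDesign(tuple(chosen))


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def _redraw_effects(truth: SimTruth, env_key: str) -> tuple:
    """Per-environment effect vectors: truth + Normal(0, gxe_sd * class RMS)."""
    a = np.asarray(truth.additive_effects, dtype=float)
    d = np.asarray(truth.dominance_effects, dtype=float)
    e = np.array([p[3] for p in truth.epistatic_pairs], dtype=float)
    rng = stream(truth.seed, f"gxe:{env_key}")
    tau_a = truth.gxe_sd["additive"] * _class_scale(a)
    tau_d = truth.gxe_sd["dominance"] * _class_scale(d)
    tau_e = truth.gxe_sd["epistasis"] * _class_scale(e)
    a_env = a + rng.normal(0.0, tau_a, size=a.shape) if a.size else a
    d_env = d + rng.normal(0.0, tau_d, size=d.shape) if d.size else d
    e_env = e + rng.normal(0.0, tau_e, size=e.shape) if e.size else e
    return a_env, d_env, e_env


def _combined_population(dh: MarkerMatrix, design: CrossingDesign | None) -> MarkerMatrix:
    from .genotype import infer_hybrid_genotypes

    if design is None or design.n_crosses == 0:
        return dh
    hybrids = infer_hybrid_genotypes(dh, design)
    return dh.concat(hybrids)


def simulate_trait(
    dh: MarkerMatrix,
    design: CrossingDesign | None,
    truth: SimTruth,
    n_env: int,
    n_rep: int,
    env_labels: Sequence[str] | None = None,
    env_key_prefix: str = "",
) -> PhenotypeTable:
    """Plot-level phenotypes for all DH lines and all hybrids.

    y(plot) = env main effect + per-environment genetic value + N(0, residual_sd).
    """
    if n_env < 1 or n_rep < 1:
        raise ConfigurationError("n_env and n_rep must be >= 1")
    if len(truth.env_effects) < n_env:
        raise ConfigurationError("truth.env_effects shorter than n_env")
    truth.validate_indices(dh.n_markers)
    pop = _combined_population(dh, design)
    if env_labels is None:
        env_labels = [f"E{k + 1}" for k in range(n_env)]
    rows = []
    for k in range(n_env):
        key = f"{env_key_prefix}{env_labels[k]}"
        a_e, d_e, e_e = _redraw_effects(truth, key)
        g = genetic_values(pop.codes, truth, a_e, d_e, e_e)
        rng = stream(truth.seed, f"plots:{key}")
        for r in range(n_rep):
            eps = rng.normal(0.0, truth.residual_sd, size=pop.n_individuals)
            y = truth.env_effects[k] + g + eps
            for i, iid in enumerate(pop.individual_ids):
                rows.append((iid, env_labels[k], r + 1, y[i]))
    df = pd.DataFrame(rows, columns=["genotype_id", "environment", "replicate", "value"])
    return PhenotypeTable(df, stage=STAGE_PLOT)


def simulate_validation_scenario(
    dh: MarkerMatrix,
    truth: SimTruth,
    n_new_parents: int,
    n_new_crosses: int,
    seed: int,
    n_rep: int = 3,
    exclude: CrossingDesign | None = None,
) -> tuple:
    """Independent validation set: fresh single crosses among the training DH
    panel plus new DH lines from the same F1, phenotyped in one fresh
    environment (new independent draws of every GxE deviation).  ``exclude``
    bars pairs already present in the training design."""
    if n_new_parents < 1 or n_new_crosses < 1:
        raise ConfigurationError("need new parents and crosses")
    new_dh = simulate_dh_population(dh.map, max(n_new_parents, 2), seed=seed + 1_000_003, id_prefix="NDH")
    new_dh = new_dh.subset_individuals(np.arange(n_new_parents))
    all_parents = dh.concat(new_dh)
    rng = stream(seed, "validation-crosses")
    old_ids = list(dh.individual_ids)
    new_ids = list(new_dh.individual_ids)
    pool = old_ids + new_ids
    crosses: list = []
    seen: set = {frozenset(c) for c in exclude.crosses} if exclude is not None else set()
    seen = set(seen)
    attempts = 0
    # parents drawn from the combined panel (existing + new lines); at least
    # one cross per new line so the new germplasm enters the validation set
    for p in new_ids:
        if len(crosses) >= n_new_crosses:
            break
        q = pool[int(rng.integers(len(pool)))]
        if p == q or frozenset((p, q)) in seen:
            continue
        crosses.append((p, q))
        seen.add(frozenset((p, q)))
    while len(crosses) < n_new_crosses:
        attempts += 1
        if attempts > 200 * n_new_crosses + 100:
            raise ConfigurationError("could not place validation crosses")
        p = pool[int(rng.integers(len(pool)))]
        q = pool[int(rng.integers(len(pool)))]
        if p == q or frozenset((p, q)) in seen:
            continue
        crosses.append((p, q))
        seen.add(frozenset((p, q)))
    design = CrossingDesign(tuple(crosses))
    from .genotype import infer_hybrid_genotypes

    hybrids = infer_hybrid_genotypes(all_parents, design)
    env_label = "VAL"
    # env main effect: a fresh draw at the scale of the training environments
    env_rng = stream(seed, "validation-env")
    env_scale = float(np.std(truth.env_effects)) if len(truth.env_effects) > 1 else 0.0
    env_eff = float(env_rng.normal(0.0, env_scale)) if env_scale > 0 else float(
        np.mean(truth.env_effects)
    )
    val_truth = SimTruth(
        qtl_positions=list(truth.qtl_positions),
        additive_effects=list(truth.additive_effects),
        dominance_effects=list(truth.dominance_effects),
        epistatic_pairs=list(truth.epistatic_pairs),
        env_effects=[env_eff],
        gxe_sd=dict(truth.gxe_sd),
        residual_sd=truth.residual_sd,
        seed=truth.seed,
    )
    pheno = simulate_trait(
        hybrids,
        None,
        val_truth,
        n_env=1,
        n_rep=n_rep,
        env_labels=[env_label],
        env_key_prefix=f"val{seed}:",
    )
    return hybrids, pheno


# ---------------------------------------------------------------------------
# Calibration against target variance components
# ---------------------------------------------------------------------------


def random_truth(
    gmap: GeneticMap,
    n_qtl: int,
    n_epi_pairs: int,
    seed: int,
    env_sd: float = 0.1,
    n_env: int = 3,
    residual_sd: float = 0.15,
    gxe_sd: dict | None = None,
) -> SimTruth:
    """Unit-scale random architecture: QTL spread over the genome, standard
    normal effects, epistatic pairs cycling through the four types."""
    rng = stream(seed, "truth")
    m = gmap.n_markers
    if n_qtl > m:
        raise ConfigurationError("more QTL than markers")
    qtl = np.sort(rng.choice(m, size=n_qtl, replace=False)).tolist()
    a = rng.normal(0.0, 1.0, size=n_qtl).tolist()
    d = rng.normal(0.0, 1.0, size=n_qtl).tolist()
    pairs = []
    pool = qtl if n_qtl >= 2 else list(range(m))
    for k in range(n_epi_pairs):
        i, j = rng.choice(len(pool), size=2, replace=False)
        pairs.append((int(pool[int(i)]), int(pool[int(j)]), EPI_TYPES[k % 4], float(rng.normal())))
    env = rng.normal(0.0, env_sd, size=n_env).tolist()
    return SimTruth(
        qtl_positions=qtl,
        additive_effects=a,
        dominance_effects=d,
        epistatic_pairs=pairs,
        env_effects=env,
        gxe_sd=dict(gxe_sd or {}),
        residual_sd=residual_sd,
        seed=seed,
    )


def _class_values(codes: np.ndarray, truth: SimTruth) -> tuple:
    zero = SimTruth(
        qtl_positions=list(truth.qtl_positions),
        additive_effects=list(truth.additive_effects),
        dominance_effects=list(truth.dominance_effects),
        epistatic_pairs=list(truth.epistatic_pairs),
        env_effects=list(truth.env_effects),
        gxe_sd=dict(truth.gxe_sd),
        residual_sd=truth.residual_sd,
        seed=truth.seed,
    )
    nq = len(truth.qtl_positions)
    zeros = np.zeros(nq)
    ezeros = np.zeros(len(truth.epistatic_pairs))
    ga = genetic_values(codes, zero, additive=None, dominance=zeros, epistatic=ezeros)
    gd = genetic_values(codes, zero, additive=zeros, dominance=None, epistatic=ezeros)
    ge = genetic_values(codes, zero, additive=zeros, dominance=zeros, epistatic=None)
    return ga, gd, ge


def calibrate_truth(
    dh: MarkerMatrix,
    design: CrossingDesign,
    truth: SimTruth,
    sigma2_g: float = 0.0267,
    shares: tuple = (0.27, 0.49, 0.24),
    sigma2_gxe: float = 0.0805,
    gxe_shares: tuple | None = None,
    sigma2_resid: float = 0.0211,
    env_sd: float = 0.1,
    n_env: int = 3,
) -> SimTruth:
    """Rescale a raw truth so the hybrid population realizes target variance
    components.

    ``shares`` are the additive/dominance/epistatic fractions of the genetic
    variance among hybrids; ``gxe_shares`` partitions the GxE variance over
    the same classes (default: proportional to ``shares``).  Residual scale
    is the plot-level error SD squared.
    """
    from .genotype import infer_hybrid_genotypes

    hybrids = infer_hybrid_genotypes(dh, design)
    ga, gd, ge = _class_values(hybrids.codes, truth)
    va, vd, ve = (float(np.var(v)) for v in (ga, gd, ge))
    sa = math.sqrt(shares[0] * sigma2_g / va) if va > 0 and shares[0] > 0 else 0.0
    sd = math.sqrt(shares[1] * sigma2_g / vd) if vd > 0 and shares[1] > 0 else 0.0
    se = math.sqrt(shares[2] * sigma2_g / ve) if ve > 0 and shares[2] > 0 else 0.0
    a = (np.asarray(truth.additive_effects) * sa).tolist()
    d = (np.asarray(truth.dominance_effects) * sd).tolist()
    pairs = [(i, j, t, eff * se) for (i, j, t, eff) in truth.epistatic_pairs]
    # per-class GxE: redrawing effect q with sd tau adds tau^2 * sum_q Var(col_q)
    # of genetic-value variance per environment (cross terms vanish in expectation)
    if gxe_shares is None:
        total = sum(shares)
        gxe_shares = tuple(s / total for s in shares)
    x = hybrids.codes[:, truth.qtl_positions] if truth.qtl_positions else np.zeros((hybrids.n_individuals, 0))
    z = (x == 0).astype(float)
    ua = float(np.sum(np.var(x, axis=0)))
    ud = float(np.sum(np.var(z, axis=0)))
    ue = 0.0
    for (i, j, typ, _) in truth.epistatic_pairs:
        xi, xj = hybrids.codes[:, i], hybrids.codes[:, j]
        zi, zj = (xi == 0).astype(float), (xj == 0).astype(float)
        col = {"AA": xi * xj, "AD": xi * zj, "DA": zi * xj, "DD": zi * zj}[typ]
        ue += float(np.var(col))
    gxe_sd = {}
    for cls, share, u, eff in (
        ("additive", gxe_shares[0], ua, a),
        ("dominance", gxe_shares[1], ud, d),
        ("epistasis", gxe_shares[2], ue, [p[3] for p in pairs]),
    ):
        scale = _class_scale(np.asarray(eff))
        if share > 0 and u > 0 and scale > 0:
            tau = math.sqrt(share * sigma2_gxe / u)
            gxe_sd[cls] = tau / scale
        else:
            gxe_sd[cls] = 0.0
    env_rng = stream(truth.seed, "env-effects")
    env = env_rng.normal(0.0, env_sd, size=n_env).tolist()
    return SimTruth(
        qtl_positions=list(truth.qtl_positions),
        additive_effects=a,
        dominance_effects=d,
        epistatic_pairs=pairs,
        env_effects=env,
        gxe_sd=gxe_sd,
        residual_sd=math.sqrt(sigma2_resid),
        seed=truth.seed,
    )
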