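"""Synthetic-world generator with known ground truth.

Builds every input the analysis pipeline needs — a realm-structured
ultrametric phylogeny, trait table, lat/lon-like environment grid, binary
occurrences and realm labels — from a single seeded configuration, so that
parameter-recovery experiments can be run without any external data.

Two independent isolation dials are exposed:

* ``mixing`` — the share of the species pool drawn from a cosmopolitan
  clade that ignores realm boundaries.  ``mixing = 0`` gives fully endemic
  realm clades (maximal compositional isolation); ``mixing = 1`` gives a
  single shared pool (no compositional isolation).
* ``isolation_rho`` — a richness-thinning factor in (0, 1]: each species
  establishes in the designated isolated realm only with probability rho
  (whole-range exclusion, like a clade that never crossed the barrier),
  independent of environment.  ``rho = 0.5`` halves expected richness
  there, emulating a deeply isolated region that is poorer than its
  environment predicts.

Environment follows a pseudo-latitudinal gradient (row coordinate of the
grid).  Species have Gaussian climatic niches on the dominant climate axis
of the realized environment table and occupy, range-map style, every cell
of their realm whose climate falls inside their tolerance window; there is
no per-cell sampling noise, mirroring presence defined by gridded range
polygons.  Niche optima are denser toward the productive end of the
gradient, which creates the richness-environment relationship.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import OccurrenceMatrix
from .functional_space import TraitTable
from .phylo_metrics import Phylogeny, read_newick

__all__ = ["WorldConfig", "World", "simulate_tree", "evolve_traits",
           "build_world", "demo_config", "recovery_config"]

_STRATA = ("aerial", "arboreal", "ground", "scansorial")


@dataclass(frozen=True)
class WorldConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_rows: int = 10
    n_cols: int = 20
    n_realms: int = 4
    realm_spans: tuple[int, ...] | None = None   # columns per realm
    species_per_realm: int = 60
    mixing: float = 0.2
    birth_rate: float = 1.0
    death_rate: float = 0.0
    bm_rate: float = 1.0
    transition_rate: float = 0.5
    niche_breadth: float = 0.3
    range_fill: tuple[float, float] = (0.05, 0.7)
    richness_env_coef: tuple[float, float] = (0.4, 0.6)
    isolation_rho: float = 1.0
    isolated_realm: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.mixing <= 1.0):
            raise ValueError("mixing must lie in [0, 1]")
        if not (0.0 < self.isolation_rho <= 1.0):
            raise ValueError("isolation_rho must lie in (0, 1]")
        for r in (self.birth_rate, self.death_rate, self.bm_rate,
                  self.transition_rate):
            if r < 0:
                raise ValueError("rates must be non-negative")
        spans = self.spans()
        if sum(spans) != self.n_cols or len(spans) != self.n_realms:
            raise ValueError("realm spans must partition the grid columns")

    def spans(self) -> tuple[int, ...]:
        if self.realm_spans is not None:
            return tuple(self.realm_spans)
        base = self.n_cols // self.n_realms
        spans = [base] * self.n_realms
        for i in range(self.n_cols - base * self.n_realms):
            spans[i] += 1
        return tuple(spans)

    def realm_names(self) -> list[str]:
        return [f"realm{i+1}" for i in range(self.n_realms)]


def demo_config(seed: int = 0) -> WorldConfig:
    """Small 30-cell / 3-realm world for demos and fast end-to-end tests."""
    return WorldConfig(n_rows=6, n_cols=5, n_realms=3, realm_spans=(2, 2, 1),
                       species_per_realm=40, mixing=0.2, isolation_rho=0.6,
                       isolated_realm=0, niche_breadth=0.3, seed=seed)


def recovery_config(rho: float, mixing: float, seed: int = 0) -> WorldConfig:
    """200-cell / 4-realm world used for parameter-recovery experiments.

    The pool (2000 species) is large enough that finite-pool roughness in
    richness along the gradient is negligible next to the gradient itself;
    with a small pool that roughness is mistaken for isolation structure
    by the flexible trend surface.
    """
    return WorldConfig(n_rows=10, n_cols=20, n_realms=4, species_per_realm=500,
                       mixing=mixing, isolation_rho=rho, isolated_realm=0,
                       seed=seed)


# ----------------------------------------------------------------------
# tree simulation
def _simulate_clade_newick(n_tips: int, labels: list[str], birth: float,
                           death: float, rng: np.random.Generator,
                           max_retries: int = 50) -> str:
    """Ultrametric birth-death clade conditioned on ``n_tips`` extant tips,
    normalized to depth 1, returned as a newick fragment (no trailing ';')."""
    if n_tips < 2:
        raise ValueError("clades need at least 2 species")
    for _ in range(max_retries):
        result = _gillespie_tree(n_tips, birth, death, rng)
        if result is not None:
            parent, t_node, alive = result
            break
    else:
        raise RuntimeError("clade simulation went extinct repeatedly")
    present = max(t_node)
    # keep only lineages ancestral to extant tips; collapse unifurcations
    children: dict[int, list[int]] = {}
    for i, p in enumerate(parent):
        if p >= 0:
            children.setdefault(p, []).append(i)
    alive_set = set(alive)
    surviving = set(alive)
    for i in sorted(range(len(parent)), key=lambda j: t_node[j], reverse=True):
        if i in surviving and parent[i] >= 0:
            surviving.add(parent[i])
    # effective root: first split with two surviving subtrees (extinction
    # can kill one side of earlier splits)
    root = 0
    while True:
        surv_kids = [k for k in children.get(root, []) if k in surviving]
        if len(surv_kids) == 1:
            root = surv_kids[0]
        else:
            break
    span = present - t_node[root]  # depth below the effective root
    tip_iter = iter(labels)

    def emit(v: int, top: float) -> str | None:
        kids = children.get(v, [])
        if not kids:
            if v not in alive_set:
                return None  # extinct tip
            return f"{next(tip_iter)}:{(present - top) / span:.10g}"
        parts = [s for k in kids if (s := emit(k, t_node[v])) is not None]
        if not parts:
            return None
        if len(parts) == 1:
            # splice the dead branch out: re-emit child with extended edge
            label, ln = parts[0].rsplit(":", 1)
            return f"{label}:{float(ln) + (t_node[v] - top) / span:.10g}"
        return "(" + ",".join(parts) + f"):{(t_node[v] - top) / span:.10g}"

    s = emit(root, t_node[root])
    assert s is not None
    # strip the clade root's zero-length stub
    return s.rsplit(":", 1)[0]


def _gillespie_tree(n_tips: int, birth: float, death: float,
                    rng: np.random.Generator):
    """Forward birth-death simulation until ``n_tips`` extant lineages."""
    parent = [-1]
    t_node = [0.0]
    alive = [0]
    t = 0.0
    while len(alive) != n_tips:
        if not alive:
            return None
        rate = len(alive) * (birth + death)
        t += rng.exponential(1.0 / rate)
        i = alive[rng.integers(len(alive))]
        if rng.random() < birth / (birth + death):
            for _ in range(2):
                parent.append(i)
                t_node.append(t)
                alive.append(len(parent) - 1)
            alive.remove(i)
            t_node[i] = t
        else:
            alive.remove(i)
            t_node[i] = t
    # extend extant tips to the present (one extra waiting time)
    t += rng.exponential(1.0 / (n_tips * max(birth + death, 1e-12)))
    for i in alive:
        t_node[i] = t
    return parent, t_node, alive


def simulate_tree(config: WorldConfig) -> tuple[Phylogeny, dict[str, str]]:
    """Realm-structured ultrametric phylogeny.

    One birth-death clade per realm (endemics) plus one cosmopolitan clade
    sized by the mixing fraction, grafted onto a common root with stem
    length 0.5 (clade depth 1, total depth 1.5).  Returns the tree and a
    tip -> realm-tag map (cosmopolitan tips tagged ``"shared"``).
    """
    rng = np.random.default_rng([config.seed, 101])
    n_endemic = round((1.0 - config.mixing) * config.species_per_realm)
    n_total = config.species_per_realm * config.n_realms
    n_cosmo = n_total - n_endemic * config.n_realms
    if n_endemic == 1:
        raise ValueError("mixing fraction leaves single-species realm clades")
    fragments = []
    realm_of: dict[str, str] = {}
    if n_endemic >= 2:
        for rname in config.realm_names():
            labels = [f"{rname}_s{i+1:03d}" for i in range(n_endemic)]
            for lab in labels:
                realm_of[lab] = rname
            fragments.append(_simulate_clade_newick(
                n_endemic, labels, config.birth_rate, config.death_rate, rng))
    if n_cosmo >= 2:
        labels = [f"shared_s{i+1:03d}" for i in range(n_cosmo)]
        for lab in labels:
            realm_of[lab] = "shared"
        fragments.append(_simulate_clade_newick(
            n_cosmo, labels, config.birth_rate, config.death_rate, rng))
    elif n_cosmo == 1:
        raise ValueError("mixing fraction leaves a single-species cosmopolitan clade")
    if not fragments:
        raise ValueError("no clades to simulate")
    if len(fragments) == 1:
        newick = fragments[0] + ";"
    else:
        newick = "(" + ",".join(f"{f}:0.5" for f in fragments) + ");"
    return read_newick(newick), realm_of


# ----------------------------------------------------------------------
# trait evolution
def _brownian(tree: Phylogeny, rate: float, rng: np.random.Generator,
              n_traits: int = 1) -> np.ndarray:
    vals = np.zeros((tree.n_nodes, n_traits))
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            continue
        sd = np.sqrt(rate * tree.edge_length[v])
        vals[v] = vals[p] + sd * rng.standard_normal(n_traits)
    return vals[: tree.n_tips]


def _ctmc_states(tree: Phylogeny, rate: float, n_states: int,
                 rng: np.random.Generator) -> np.ndarray:
    states = np.zeros(tree.n_nodes, dtype=int)
    states[:] = -1
    root_state = rng.integers(n_states)
    for v in tree.preorder:
        p = tree.parent[v]
        if p < 0:
            states[v] = root_state
            continue
        s = states[p]
        if rate > 0:
            remaining = tree.edge_length[v]
            while True:
                wait = rng.exponential(1.0 / rate)
                if wait > remaining:
                    break
                remaining -= wait
                s = (s + 1 + rng.integers(n_states - 1)) % n_states
        states[v] = s
    return states[: tree.n_tips]


def evolve_traits(tree: Phylogeny, config: WorldConfig,
                  rng: np.random.Generator | None = None) -> TraitTable:
    """Traits evolved along the tree.

    Continuous traits by Brownian motion (body mass on the log scale), a
    percentage diet block via softmax of correlated Brownian deviates (rows
    sum to 100), and a categorical foraging stratum by a continuous-time
    Markov chain.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 202])
    log_mass = 3.0 + _brownian(tree, config.bm_rate, rng)[:, 0]
    trophic = _brownian(tree, config.bm_rate, rng)[:, 0]
    diet_names = ["diet_invertebrates", "diet_vertebrates", "diet_fruit",
                  "diet_seeds", "diet_plants"]
    diet_bm = _brownian(tree, config.bm_rate, rng, n_traits=len(diet_names))
    expd = np.exp(2.0 * diet_bm)
    diet = expd / expd.sum(axis=1, keepdims=True) * 100.0
    strata = _ctmc_states(tree, config.transition_rate, len(_STRATA), rng)
    data = pd.DataFrame({"body_mass": np.exp(log_mass),
                         "trophic_position": trophic},
                        index=tree.tip_labels)
    for j, name in enumerate(diet_names):
        data[name] = diet[:, j]
    data["foraging_stratum"] = [_STRATA[s] for s in strata]
    schema = {"body_mass": {"kind": "continuous", "transform": "log"},
              "trophic_position": {"kind": "continuous"},
              "foraging_stratum": {"kind": "categorical"}}
    for name in diet_names:
        schema[name] = {"kind": "percentage"}
    return TraitTable(data, schema)


def _linear_density_optima(u: np.ndarray, a: float, b: float,
                           pad: float) -> np.ndarray:
    """Inverse-CDF sample of niche optima on [-pad, 1 + pad].

    Density is a + b*(1 - o) on [0, 1] and continues flat beyond the
    interval (a + b below 0, a above 1), so the within-grid gradient keeps
    its full slope while boundary neighborhoods stay populated.
    """
    mass_left = pad * (a + b)
    mass_mid = a + 0.5 * b
    mass_right = pad * a
    total = mass_left + mass_mid + mass_right
    t = u * total
    out = np.empty_like(t)
    left = t < mass_left
    out[left] = t[left] / (a + b) - pad
    mid = (~left) & (t < mass_left + mass_mid)
    if b > 0:
        f = t[mid] - mass_left  # CDF value into a*o + b*(o - o^2/2)
        out[mid] = ((a + b) - np.sqrt((a + b) ** 2 - 2.0 * b * f)) / b
    else:
        out[mid] = (t[mid] - mass_left) / a
    right = t >= mass_left + mass_mid
    out[right] = 1.0 + (t[right] - mass_left - mass_mid) / a
    return out


# ----------------------------------------------------------------------
@dataclass
class World:
    """A complete synthetic input bundle plus its ground-truth record."""

    config: WorldConfig
    tree: Phylogeny
    realm_of_tip: dict[str, str]
    traits: TraitTable
    occurrences: OccurrenceMatrix
    environment: pd.DataFrame
    realm_labels: pd.Series
    truth: dict

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "tree.nwk").write_text(self.tree.to_newick() + "\n")
        self.occurrences.to_csv(outdir / "occurrences.csv")
        self.traits.to_csv(outdir / "traits.csv", outdir / "traits_schema.json")
        self.environment.to_csv(outdir / "environment.csv", float_format="%.10g")
        self.realm_labels.rename("realm").to_csv(outdir / "realms.csv")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1, sort_keys=True)


def _environment_table(config: WorldConfig, lat: np.ndarray,
                       cells: list[str], rng: np.random.Generator) -> pd.DataFrame:
    n = len(cells)
    env = pd.DataFrame(index=pd.Index(cells, name="cell"))
    env["temp_mean"] = 30.0 - 25.0 * lat + rng.normal(0, 1.0, n)
    env["temp_seasonality"] = 10.0 + 20.0 * lat + rng.normal(0, 2.0, n)
    env["temp_range"] = 8.0 + 15.0 * lat + rng.normal(0, 2.0, n)
    # precipitation-like variables built skewed (squared), so the pipeline's
    # sqrt transform is the appropriate de-skew
    env["precip_total"] = np.clip(12.0 * (1 - lat) + 3.0 + rng.normal(0, 1.0, n), 0.1, None) ** 2
    env["precip_seasonality"] = np.clip(8.0 * (1 - lat) + 2.0 + rng.normal(0, 1.0, n), 0.1, None) ** 2
    env["precip_driest"] = np.clip(6.0 * (1 - lat) + 1.0 + rng.normal(0, 1.0, n), 0.1, None) ** 2
    env["mean_elevation"] = np.abs(rng.normal(600.0, 400.0, n))
    env["elevation_range"] = rng.uniform(100.0, 2000.0, n)
    env["landmass_area"] = np.exp(rng.normal(13.0, 0.7, n))
    return env


def build_world(config: WorldConfig) -> World:
    """Generate the full synthetic world for a configuration (deterministic
    under the configuration's master seed)."""
    tree, realm_of = simulate_tree(config)
    traits = evolve_traits(tree, config,
                           np.random.default_rng([config.seed, 202]))
    rng_env = np.random.default_rng([config.seed, 303])
    rng_occ = np.random.default_rng([config.seed, 404])

    spans = config.spans()
    realm_names = config.realm_names()
    col_realm = np.repeat(np.arange(config.n_realms), spans)
    cells, lat_list, realm_idx = [], [], []
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            cells.append(f"r{r:02d}c{c:02d}")
            lat_list.append(r / max(config.n_rows - 1, 1))
            realm_idx.append(col_realm[c])
    lat = np.array(lat_list)
    realm_idx = np.array(realm_idx)
    env = _environment_table(config, lat, cells, rng_env)
    realm_labels = pd.Series([realm_names[i] for i in realm_idx],
                             index=cells, name="realm")

    species = tree.tip_labels
    n_sp = len(species)
    optima = rng_occ.uniform(0.0, 1.0, n_sp)
    breadths = config.niche_breadth * rng_occ.uniform(0.7, 1.3, n_sp)
    a_coef, b_coef = config.richness_env_coef
    # occupancy is driven by the dominant climate axis of the realized
    # environment table (first principal component of the climate columns,
    # min-max rescaled to [0, 1]): the species' niche axis is the major
    # climate gradient itself, so the written table contains the true
    # driver of richness
    from .inference import climate_pca
    scores, _, _ = climate_pca(
        env, [c for c in env.columns if c.startswith("precip")], 2)
    pc1 = scores["PC1"].to_numpy()
    z = (pc1 - pc1.min()) / (pc1.max() - pc1.min())
    # richness-environment gradient: niche optima are denser toward the
    # productive end of the gradient, with linear density a + b*(1 - o) on
    # the grid interval [0, 1].  The optimum domain is padded by the
    # maximum tolerance width on both sides, extending the density flat
    # beyond the interval, so every grid position sees an unclipped niche
    # neighborhood: expected richness varies linearly along the gradient,
    # with no boundary droop for the regression stage to mistake for
    # isolation structure.
    pad = (config.niche_breadth * 1.3
           * np.sqrt(-2.0 * np.log(config.range_fill[0])))
    optima = _linear_density_optima(optima, a_coef, b_coef, pad)
    # range-map model: a species occupies every cell whose niche-axis
    # position falls inside its climatic tolerance window; presence is
    # deterministic given the species-level draws (like gridded range
    # polygons, there is no per-cell sampling noise)
    fill = rng_occ.uniform(*config.range_fill, n_sp)
    widths = breadths * np.sqrt(-2.0 * np.log(fill))
    occ = (np.abs(z[:, None] - optima[None, :]) <= widths[None, :])
    # realm endemism mask: endemics occur only in their realm's columns
    sp_realm = np.array([realm_of[s] for s in species])
    for i, rname in enumerate(realm_names):
        occ[np.ix_(realm_idx != i, sp_realm == rname)] = False
    # isolation: each species independently fails to establish in the
    # designated realm with probability 1 - rho (whole-range exclusion,
    # like a clade that never crossed the barrier)
    excluded = rng_occ.random(n_sp) > config.isolation_rho
    occ[np.ix_(realm_idx == config.isolated_realm, excluded)] = False
    flagged = [cells[i] for i in np.flatnonzero(occ.sum(axis=1) == 0)]
    occurrences = OccurrenceMatrix(cells, species, occ.astype(np.uint8))

    truth = {
        "config": dataclasses.asdict(config),
        "rho": config.isolation_rho,
        "mixing": config.mixing,
        "isolated_realm": realm_names[config.isolated_realm],
        "niche_optima": {s: float(o) for s, o in zip(species, optima)},
        "niche_breadths": {s: float(b) for s, b in zip(species, breadths)},
        "niche_widths": {s: float(wd) for s, wd in zip(species, widths)},
        "species_excluded_from_isolated_realm":
            [s for s, e in zip(species, excluded) if e],
        "stage_seeds": {"tree": [config.seed, 101], "traits": [config.seed, 202],
                        "environment": [config.seed, 303],
                        "occupancy": [config.seed, 404]},
        "empty_cells_flagged": flagged,
    }
    truth["config"]["realm_spans"] = list(spans)
    return World(config, tree, realm_of, traits, occurrences, env,
                 realm_labels, truth)
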