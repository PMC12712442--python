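"""Synthetic data with known ground truth for every pipeline stage.

Generates pure-birth trees with clustered genus labels, lambda-transformed
Brownian traits with controllable evolutionary correlation, phylogenetically
clustered functional-group labels, quantile-regression responses with
asymmetric-Laplace noise (so the generating group lines are exactly the
conditional tau-quantiles), raw electrolyte-leakage curves, raw frost and
drought measurement tables whose correct curation output is computable a
priori, and spatially clustered occurrences over closed-form climate
gradients.  Every generator is deterministic given its seed, and each
dataset ships with a truth record sufficient to score parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .climate import ClimateGrid
from .quantreg import QRData, al_rvs
from .trees import lambda_transform, vcv

__all__ = [
    "SimConfig", "sim_tree", "sim_two_clade_tree", "sim_bm_traits",
    "sim_correlated_traits",
    "sim_group_labels", "sim_qr_dataset", "sim_el_curve",
    "sim_raw_measurement_tables", "sim_occurrences_and_grids",
]

GROUPS = ("deciduous_angiosperm", "evergreen_angiosperm", "gymnosperm")


@dataclass
class SimConfig:
    """Ground-truth parameters of a synthetic study.

    Defaults emulate the structure of the real comparative dataset: a few
    hundred species, strong phylogenetic signal in both resistance traits,
    LT50-like responses (deg C) regressed on P50-like predictors (MPa) with
    group-specific lines, asymmetric-Laplace residuals at a known quantile,
    and a phylogenetic random effect of the same order as the residual scale.
    """

    n_species: int = 200
    birth_rate: float = 1.0
    lambda_true: float = 1.0
    sigma2: float = 1.0          # trait variance per unit branch length
    rho_evol: float = 0.0        # evolutionary correlation between two traits
    # quantile-regression truth (y ~ LT50 in degC, x ~ P50 in MPa)
    tau: float = 0.5
    alpha_g: dict = field(default_factory=lambda: {
        "deciduous_angiosperm": -30.0,
        "evergreen_angiosperm": -12.0,
        "gymnosperm": -22.0})
    beta_g: dict = field(default_factory=lambda: {
        "deciduous_angiosperm": 1.5,
        "evergreen_angiosperm": 2.5,
        "gymnosperm": 1.0})
    sigma: float = 3.0           # AL residual scale, degC
    sigma_p: float = 3.0         # phylo effect SD, degC
    x_root: float = -4.0         # root state of the predictor BM, MPa
    x_sigma2: float = 6.0        # predictor BM rate on the unit-height tree
    # electrolyte-leakage curve truth
    el_baseline: float = 8.0
    el_plateau: float = 92.0
    el_lt50: float = -22.0
    el_slope: float = 0.4
    el_noise_sd: float = 3.0
    # occurrences / climate grids
    n_occ_per_species: int = 300
    occ_spread_deg: float = 1.5
    seed: int = 0


# ---------------------------------------------------------------------------
# trees and traits

def sim_tree(n: int, birth_rate: float = 1.0, seed: int = 0,
             max_genus_size: int = 6) -> dendropy.Tree:
    """Pure-birth ultrametric tree with clustered genus labels.

    Tips are labelled "Genus<k> sp<j>", with genera assigned to the maximal
    clades of at most ``max_genus_size`` tips so that genus-level grafting is
    exercised on realistic clusters.  Deterministic given ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    # Yule process: waiting time to the next split ~ Exp(k * birth_rate)
    # with k extant lineages; a uniformly chosen lineage splits.  A final
    # waiting interval after the n-th lineage appears keeps terminal
    # branches strictly positive, and extending every open lineage to the
    # stopping time makes the tree ultrametric.
    taxon_namespace = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.is_rooted = True
    root = tree.seed_node
    t = 0.0
    open_lineages = []
    for _ in range(2):
        child = root.new_child(edge_length=0.0)
        open_lineages.append((child, t))
    k = 2
    while k < n:
        t += rng.exponential(1.0 / (k * birth_rate))
        i = int(rng.integers(k))
        node, born = open_lineages.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            open_lineages.append((node.new_child(edge_length=0.0), t))
        k += 1
    t += rng.exponential(1.0 / (k * birth_rate))
    for node, born in open_lineages:
        node.edge.length = t - born
        node.taxon = taxon_namespace.new_taxon(label="tmp")
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i}"
    # clade sizes
    sizes: dict = {}
    for node in tree.postorder_node_iter():
        sizes[node] = 1 if node.is_leaf() else sum(
            sizes[c] for c in node.child_nodes())
    genus_idx = 0
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if sizes[node] <= max_genus_size and (
                parent is None or sizes[parent] > max_genus_size):
            genus_idx += 1
            for j, leaf in enumerate(node.leaf_iter(), start=1):
                leaf.taxon.label = f"Genus{genus_idx} sp{j}"
    return tree


def sim_two_clade_tree(n: int, stem_mult: float = 6.0, seed: int = 0
                       ) -> dendropy.Tree:
    """Two Yule clades joined by deep basal stems (ultrametric).

    Emulates phylogenies dominated by an ancient divergence (such as the
    gymnosperm/angiosperm split): each half is a pure-birth clade and the
    two basal stems are ``stem_mult`` times the clade height, so most of the
    expected trait variance accrues on the shared deep branches.  This is
    the regime in which two independently evolving traits show strong
    spurious cross-species correlation.
    """
    from .trees import read_newick, write_newick
    a = sim_tree(n // 2, seed=seed)
    b = sim_tree(n - n // 2, seed=seed + 77)
    for lf in b.leaf_node_iter():
        lf.taxon.label = lf.taxon.label.replace("Genus", "Xgenus")
    ha = max(lf.distance_from_root() for lf in a.leaf_node_iter())
    hb = max(lf.distance_from_root() for lf in b.leaf_node_iter())
    na = "(" + write_newick(a).rstrip(";").strip() + f"):{stem_mult * ha}"
    nb = ("(" + write_newick(b).rstrip(";").strip()
          + f"):{stem_mult * ha + ha - hb}")
    return read_newick(f"({na},{nb});")


def sim_bm_traits(tree: dendropy.Tree, sigma2: float = 1.0,
                  lambda_true: float = 1.0, root_value: float = 0.0,
                  seed: int = 0) -> pd.Series:
    """One draw from MVN(root, sigma2 * C(lambda)) over the tips."""
    C = lambda_transform(vcv(tree), lambda_true)
    rng = np.random.default_rng(seed)
    cov = sigma2 * C.matrix
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(C.n) * max(np.trace(cov), 1.0))
    x = root_value + L @ rng.standard_normal(C.n)
    return pd.Series(x, index=list(C.species), name="trait")


def sim_correlated_traits(tree: dendropy.Tree,
                          sigma2_pair: tuple[float, float] = (1.0, 1.0),
                          rho_evol: float = 0.0, seed: int = 0,
                          roots: tuple[float, float] = (0.0, 0.0)
                          ) -> pd.DataFrame:
    """Bivariate Brownian motion: per-branch increments are bivariate normal
    with evolutionary correlation ``rho_evol``."""
    if not -1.0 <= rho_evol <= 1.0:
        raise ValueError("rho_evol must lie in [-1, 1]")
    s1, s2 = sigma2_pair
    Sigma = np.array([[s1, rho_evol * np.sqrt(s1 * s2)],
                      [rho_evol * np.sqrt(s1 * s2), s2]])
    L = np.linalg.cholesky(Sigma + 1e-12 * np.eye(2))
    rng = np.random.default_rng(seed)
    states = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            states[node] = np.array(roots, dtype=float)
            continue
        bl = node.edge.length or 0.0
        states[node] = states[parent] + np.sqrt(bl) * (L @ rng.standard_normal(2))
    rows = {lf.taxon.label: states[lf] for lf in tree.leaf_node_iter()}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=["trait1", "trait2"])


def sim_group_labels(tree: dendropy.Tree, seed: int = 0,
                     groups: tuple[str, ...] = GROUPS) -> pd.Series:
    """Phylogenetically clustered group labels.

    A latent Brownian liability evolves on the tree and is cut at its
    empirical terciles — a threshold-model discretization that mirrors how
    strongly the real functional groups (gymnosperms vs angiosperms) track
    the phylogeny.
    """
    liab = sim_bm_traits(tree, sigma2=1.0, lambda_true=1.0, seed=seed)
    cuts = np.quantile(liab.to_numpy(), np.linspace(0, 1, len(groups) + 1)[1:-1])
    codes = np.searchsorted(cuts, liab.to_numpy())
    return pd.Series([groups[c] for c in codes], index=liab.index, name="group")


# ---------------------------------------------------------------------------
# quantile-regression datasets

def sim_qr_dataset(tree: dendropy.Tree | None, config: SimConfig,
                   seed: int | None = None) -> tuple[QRData, dict]:
    """Simulate y_i = alpha_g + beta_g x_i + u_i + eps_i with AL(tau) noise.

    With a tree, groups are phylogenetically clustered, x is Brownian on the
    unit-height tree and u ~ MVN(0, sigma_p^2 C_std); without a tree, groups
    are balanced-random, x is Gaussian and u = 0.  By construction the
    generating line is the conditional tau-quantile of y given x.  Returns
    the dataset and a truth dict holding every generating parameter and
    latent value.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if tree is not None:
        C = vcv(tree).standardized()
        species = tuple(C.species)
        n = len(species)
        group = sim_group_labels(tree, seed=seed + 1).loc[list(species)].to_numpy()
        Lx = np.linalg.cholesky(
            config.x_sigma2 * C.matrix + 1e-10 * np.eye(n))
        x = config.x_root + Lx @ rng.standard_normal(n)
        if config.sigma_p > 0:
            Lu = np.linalg.cholesky(C.matrix + 1e-10 * np.eye(n))
            u = config.sigma_p * (Lu @ rng.standard_normal(n))
        else:
            u = np.zeros(n)
    else:
        C = None
        n = config.n_species
        species = tuple(f"sp{i}" for i in range(n))
        group = np.array([GROUPS[i % len(GROUPS)] for i in range(n)])
        rng.shuffle(group)
        x = config.x_root + np.sqrt(config.x_sigma2) * rng.standard_normal(n)
        u = np.zeros(n)
    alpha = np.array([config.alpha_g[g] for g in group])
    beta = np.array([config.beta_g[g] for g in group])
    eps = al_rvs(rng, n, config.sigma, config.tau)
    y = alpha + beta * x + u + eps
    data = QRData(y=y, x=x, group=group, C=C, species=species)
    truth = {
        "tau": config.tau,
        "alpha_g": dict(config.alpha_g),
        "beta_g": dict(config.beta_g),
        "sigma": config.sigma,
        "sigma_p": config.sigma_p if tree is not None else 0.0,
        "u": u.tolist(),
        "species": list(species),
        "group": group.tolist(),
    }
    return data, truth


# ---------------------------------------------------------------------------
# raw measurement generators

def sim_el_curve(config: SimConfig, temperatures, noise_sd: float | None = None,
                 seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Logistic REL(T) curve plus iid Gaussian noise, clipped to [0, 100]."""
    T = np.asarray(temperatures, dtype=float)
    if T.shape[0] < 5:
        raise ValueError("need at least 5 temperatures")
    noise_sd = config.el_noise_sd if noise_sd is None else noise_sd
    rng = np.random.default_rng(seed)
    mean = config.el_baseline + (config.el_plateau - config.el_baseline) / (
        1.0 + np.exp(config.el_slope * (T - config.el_lt50)))
    rel = np.clip(mean + noise_sd * rng.standard_normal(T.shape[0]), 0.0, 100.0)
    return T, rel


# frost metadata scenarios: which (method, organ) cells a species carries
_FROST_SCENARIOS = [
    [("EL", "branch")],
    [("EL", "branch"), ("VS", "leaf")],
    [("EL", "bud"), ("VS", "branch")],
    [("VS", "branch")],
    [("VS", "bud"), ("VS", "leaf")],
    [("EL", "leaf")],
    [("VS", "leaf")],
    [("EL", "branch"), ("EL", "bud"), ("VS", "branch")],
]

_P50_SCENARIOS = [
    [("centrifuge", "stem"), ("optical", "stem")],
    [("centrifuge", "stem")],
    [("bench_dehydration", "stem"), ("air_injection", "stem")],
    [("optical", "leaf")],
    [("air_injection", "stem")],
    [("microCT", "stem"), ("bench_dehydration", "stem")],
]


def sim_raw_measurement_tables(truth: pd.DataFrame, seed: int = 0,
                               cell_sd: float = 1.0, n_rep: int = 2
                               ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Raw frost and drought tables whose curated output is known a priori.

    ``truth`` needs columns species, lt50_true, p50_true.  Each species is
    assigned a metadata scenario (which organ/method cells exist); cell
    values scatter around the true trait with SD ``cell_sd`` and ``n_rep``
    replicate rows per cell.  Rows are given midwinter dates, in-bounds
    rates, sigmoid curve shapes and consistent turgor-loss points, plus a
    handful of decoy rows that every filter must remove.  Returns
    (frost_rows, drought_rows, expected) where ``expected`` holds the exact
    curated value and category/tier per species.
    """
    rng = np.random.default_rng(seed)
    from .curation import FROST_PRIORITY

    frost_rows, drought_rows, expected = [], [], []
    for _, rec in truth.iterrows():
        sp = rec["species"]
        # ---- frost
        scenario = _FROST_SCENARIOS[int(rng.integers(len(_FROST_SCENARIOS)))]
        cell_means = {}
        for method, organ in scenario:
            vals = rec["lt50_true"] + cell_sd * rng.standard_normal(n_rep)
            cell_means[(method, organ)] = float(np.mean(vals))
            for v in vals:
                frost_rows.append({
                    "species": sp, "organ": organ, "method": method,
                    "value_C": float(v), "date": "2015-01-15", "lat": 45.0,
                    "rate_C_per_h": float(rng.uniform(0.5, 8.0)),
                    "age_class": "adult"})
        # decoys: out-of-window date and out-of-bounds rate
        frost_rows.append({"species": sp, "organ": "branch", "method": "EL",
                           "value_C": 5.0, "date": "2015-07-15", "lat": 45.0,
                           "rate_C_per_h": 1.0, "age_class": "adult"})
        frost_rows.append({"species": sp, "organ": "branch", "method": "EL",
                           "value_C": 5.0, "date": "2015-01-20", "lat": 45.0,
                           "rate_C_per_h": 0.1, "age_class": "adult"})
        best = min(FROST_PRIORITY[c] for c in scenario)
        best_cell = next(c for c in scenario if FROST_PRIORITY[c] == best)
        # ---- drought
        pscen = _P50_SCENARIOS[int(rng.integers(len(_P50_SCENARIOS)))]
        tier_values: dict[str, list[float]] = {}
        tlp = rec["p50_true"] + 1.0  # TLP less negative than P50: consistent
        for technique, organ in pscen:
            v = float(rec["p50_true"] + 0.2 * cell_sd * rng.standard_normal())
            drought_rows.append({
                "species": sp, "organ": organ, "technique": technique,
                "curve_shape": "sigmoid", "p50_MPa": v, "psi_tlp_MPa": tlp})
            if organ == "stem" and technique in ("centrifuge", "optical", "microCT"):
                tier = "tier1"
            elif organ == "stem" and technique == "bench_dehydration":
                tier = "tier2"
            elif organ == "leaf":
                tier = "tier3"
            else:
                tier = "tier4"
            tier_values.setdefault(tier, []).append(v)
        # decoy: r-shaped curve that the shape filter must drop
        drought_rows.append({"species": sp, "organ": "stem",
                             "technique": "centrifuge", "curve_shape": "r_shaped",
                             "p50_MPa": -0.1, "psi_tlp_MPa": tlp})
        tier = sorted(tier_values)[0]
        expected.append({
            "species": sp,
            "lt50": cell_means[best_cell], "lt50_category": best,
            "p50": float(np.mean(tier_values[tier])), "p50_source": tier})
    return (pd.DataFrame(frost_rows), pd.DataFrame(drought_rows),
            pd.DataFrame(expected).sort_values("species").reset_index(drop=True))


# ---------------------------------------------------------------------------
# occurrences and climate grids

def sim_occurrences_and_grids(
    species: list[str], config: SimConfig, seed: int = 0,
    extent: tuple[float, float, float, float] = (-20.0, 20.0, 20.0, 60.0),
    cellsize: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, ClimateGrid], dict]:
    """Gaussian occurrence clouds over smooth closed-form climate gradients.

    The aridity index increases linearly with longitude and minimum
    temperature decreases linearly with latitude, so every range percentile
    has a computable truth.  Returns (occurrences, grids, truth) where truth
    records the gradient coefficients and each species' range center.
    """
    lon0, lon1, lat0, lat1 = extent
    rng = np.random.default_rng(seed)
    ncols = int(round((lon1 - lon0) / cellsize))
    nrows = int(round((lat1 - lat0) / cellsize))
    lon_c = lon0 + (np.arange(ncols) + 0.5) * cellsize
    lat_c = lat1 - (np.arange(nrows) + 0.5) * cellsize  # row 0 = north
    LON, LAT = np.meshgrid(lon_c, lat_c)
    coef = {"ai": {"a0": 1.2, "a_lon": 0.02},      # wetter eastward
            "tmin": {"b0": 10.0, "b_lat": -0.8},    # colder northward
            "map": {"m0": 900.0, "m_lon": 15.0},
            "mat": {"t0": 25.0, "t_lat": -0.45}}
    grids = {
        "ai": ClimateGrid(lon0, lat0, cellsize,
                          coef["ai"]["a0"] + coef["ai"]["a_lon"] * LON),
        "tmin": ClimateGrid(lon0, lat0, cellsize,
                            coef["tmin"]["b0"] + coef["tmin"]["b_lat"] * (LAT - lat0)),
        "map": ClimateGrid(lon0, lat0, cellsize,
                           coef["map"]["m0"] + coef["map"]["m_lon"] * LON),
        "mat": ClimateGrid(lon0, lat0, cellsize,
                           coef["mat"]["t0"] + coef["mat"]["t_lat"] * (LAT - lat0)),
    }
    rows = []
    centers = {}
    margin = 4.0
    for sp in species:
        cx = float(rng.uniform(lon0 + margin, lon1 - margin))
        cy = float(rng.uniform(lat0 + margin, lat1 - margin))
        centers[sp] = (cx, cy)
        lon = np.clip(cx + config.occ_spread_deg * rng.standard_normal(
            config.n_occ_per_species), lon0 + cellsize, lon1 - cellsize)
        lat = np.clip(cy + config.occ_spread_deg * rng.standard_normal(
            config.n_occ_per_species), lat0 + cellsize, lat1 - cellsize)
        rows.extend({"species": sp, "lon": float(a), "lat": float(b)}
                    for a, b in zip(lon, lat))
    truth = {"coef": coef, "centers": centers, "extent": extent,
             "cellsize": cellsize}
    return pd.DataFrame(rows), grids, truth
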