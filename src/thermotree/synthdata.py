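"""Synthetic inputs with known ground truth.

Every downstream stage of the pipeline can be exercised without any field
or remote-sensing data: this module generates ultrametric phylogenies with
family structure, traits evolving under a stationary Ornstein-Uhlenbeck
(OU) process with an additive elevation effect, ramping-assay records
discretized to the 1 degC / 2 min protocol grid, diurnal microclimate series
with an elevational lapse, static knockdown times following the log-linear
thermal-death-time law, and family-structured protein melting-temperature
tables.

All generators draw from named substreams of a single root seed, so adding
a generator never perturbs the streams of the others, and a fixed
:class:`SimConfig` reproduces its outputs byte-identically.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .tdt import TDTParams, TemperatureSeries
from .trees import CalibratedTree

__all__ = [
    "TraitParams",
    "AssayParams",
    "ClimateParams",
    "SimConfig",
    "substream",
    "simulate_tree",
    "simulate_trait_ou",
    "simulate_trait_lambda",
    "simulate_assay_records",
    "simulate_shock_experiment",
    "simulate_community_assays",
    "simulate_microclimate",
    "simulate_static_knockdowns",
    "simulate_tm_table",
    "generate_all",
]


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class TraitParams:
    """Generative model of tip CT_max (degC).

    ``beta0`` is the trait optimum at elevation 0 (the OU optimum theta
    when ``beta_elev == 0``); ``beta_elev`` the additive elevation effect
    in degC per metre; ``alpha`` the pull strength (1/time, 0 reduces the
    deviation process exactly to Brownian motion); ``sigma2`` the diffusion
    variance (degC^2 per unit time).
    """

    beta0: float = 42.2
    beta_elev: float = -0.0023
    alpha: float = 3.0
    sigma2: float = 6.0

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")


@dataclass
class AssayParams:
    """Ramping protocol: start at 28 degC, 1 degC steps checked every 2 min."""

    start_temp: float = 28.0
    step: float = 1.0
    interval_min: float = 2.0

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be > 0")

    @property
    def ramp_rate(self) -> float:
        """degC per minute."""
        return self.step / self.interval_min


@dataclass
class ClimateParams:
    """Diurnal + seasonal microclimate with an elevational lapse.

    Defaults emulate a wet tropical lowland: 24.3 degC mean at sea level,
    4.9 degC/km lapse, 5 degC diurnal half-amplitude, weak annual
    seasonality, and AR(1) weather noise with marginal sd 1 degC.
    """

    sea_level_mean: float = 24.3
    lapse_per_m: float = 0.0049
    diurnal_amplitude: float = 5.0
    seasonal_amplitude: float = 1.0
    ar1: float = 0.8
    noise_sd: float = 1.0


@dataclass
class SimConfig:
    """One knob for every generator; the root seed fixes all streams."""

    seed: int = 0
    n_tips: int = 200
    n_families: int = 20
    tree_depth: float = 1.0
    elevation_grid: tuple = (250.0, 750.0, 1250.0, 1750.0, 2250.0, 2750.0)
    trait_params: TraitParams = field(default_factory=TraitParams)
    assay_params: AssayParams = field(default_factory=AssayParams)
    climate_params: ClimateParams = field(default_factory=ClimateParams)
    tdt_truth: TDTParams = field(default_factory=lambda: TDTParams(z=3.0, t_l=46.0))
    within_species_sd: float = 1.0

    def __post_init__(self):
        if self.n_tips < 1:
            raise ValueError("n_tips must be >= 1")


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from ``(seed, name)``.

    Uses a CRC32 hash of the name in the seed sequence so streams are
    stable across runs, platforms, and additions of new generators.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# phylogeny
# ---------------------------------------------------------------------------


class _Lineage:
    __slots__ = ("birth", "parent", "family", "order")

    def __init__(self, birth, parent, family=None, order=None):
        self.birth = birth
        self.parent = parent
        self.family = family
        self.order = order


def simulate_tree(
    n_tips: int,
    seed: int,
    depth: float = 1.0,
    n_families: int | None = None,
    n_orders: int | None = None,
) -> CalibratedTree:
    """Pure-birth ultrametric tree with tips ``OTU_1..n`` and clade families.

    Lineages split at unit rate; the tree is rescaled so all root-to-tip
    paths equal ``depth``.  Families (and orders) are assigned by the clades
    present when the lineage count first reaches ``n_families``
    (``n_orders``), i.e. by cutting the tree at that height.
    """
    if n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    if n_tips == 1:
        return CalibratedTree.from_newick(
            "OTU_1:0.0;", family={"OTU_1": "F01"}, order={"OTU_1": "O1"}
        )
    n_families = min(n_families or max(2, n_tips // 10), n_tips)
    n_orders = min(n_orders or min(6, n_families), n_families)
    rng = substream(seed, "tree")

    nodes: list = []  # (time, parent_index) — children list built later
    children: dict = {}

    def new_node(time, parent):
        nodes.append(time)
        idx = len(nodes) - 1
        children.setdefault(parent, []).append(idx)
        return idx

    root_idx = new_node(0.0, None)
    # the reconstructed tree starts at the root split: two lineages at t=0
    active = [_Lineage(0.0, root_idx), _Lineage(0.0, root_idx)]
    t = 0.0
    fam_counter = [0]
    ord_counter = [0]
    while len(active) < n_tips:
        k = len(active)
        t += rng.exponential(1.0 / k)
        i = int(rng.integers(k))
        lin = active.pop(i)
        node = new_node(t, lin.parent)
        for _ in range(2):
            active.append(_Lineage(t, node, lin.family, lin.order))
        if len(active) == n_orders and ord_counter[0] == 0:
            for j, ln in enumerate(active):
                ln.order = f"O{j + 1}"
            ord_counter[0] = n_orders
        if len(active) == n_families and fam_counter[0] == 0:
            for j, ln in enumerate(active):
                ln.family = f"F{j + 1:02d}"
            fam_counter[0] = n_families
    present = t + rng.exponential(1.0 / n_tips)

    family_map, order_map = {}, {}
    tip_labels = {}
    for j, lin in enumerate(active):
        label = f"OTU_{j + 1}"
        idx = new_node(present, lin.parent)
        tip_labels[idx] = label
        family_map[label] = lin.family or "F01"
        order_map[label] = lin.order or "O1"

    scale = depth / present

    # serialize with branch lengths (child time - parent time, rescaled)
    def serialize_with_parent(idx, parent_time) -> str:
        kids = children.get(idx)
        if not kids:
            base = tip_labels[idx]
        else:
            base = (
                "("
                + ",".join(serialize_with_parent(c, nodes[idx]) for c in kids)
                + ")"
            )
        return base + ":" + format((nodes[idx] - parent_time) * scale, ".17g")

    newick = serialize_with_parent(root_idx, 0.0) + ";"
    return CalibratedTree.from_newick(newick, family=family_map, order=order_map)


# ---------------------------------------------------------------------------
# traits
# ---------------------------------------------------------------------------


def simulate_trait_ou(
    tree: CalibratedTree,
    params: TraitParams,
    elevations,
    seed: int,
) -> pd.Series:
    """Tip trait = beta0 + beta_elev * elevation + OU deviation around 0.

    The deviation process starts at stationarity: the root value is drawn
    from N(0, sigma2 / (2 alpha)), and each branch of length ``t`` applies
    the exact OU transition ``u -> u e^{-alpha t} + N(0, sigma2 (1 -
    e^{-2 alpha t}) / (2 alpha))``.  With ``alpha = 0`` the recursion is the
    exact Brownian-motion transition (root at 0, variance ``sigma2 t``).
    """
    labels = tree.tip_labels
    elev = _align_elevations(elevations, labels)
    rng = substream(seed, "trait-ou")
    a, s2 = params.alpha, params.sigma2
    u: dict = {}
    for node in tree.tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            u[node] = rng.normal(0.0, np.sqrt(s2 / (2 * a))) if a > 0 else 0.0
            continue
        t = node.edge.length or 0.0
        if a > 0:
            mean = u[parent] * np.exp(-a * t)
            var = s2 * (1 - np.exp(-2 * a * t)) / (2 * a)
        else:
            mean = u[parent]
            var = s2 * t
        u[node] = mean + rng.normal(0.0, np.sqrt(var)) if var > 0 else mean
    dev = np.array([u[leaf] for leaf in tree.tree.leaf_node_iter()])
    return pd.Series(params.beta0 + params.beta_elev * elev + dev, index=labels)


def simulate_trait_lambda(
    tree: CalibratedTree,
    lam: float,
    sigma2: float = 1.0,
    mean: float = 0.0,
    seed: int = 0,
) -> pd.Series:
    """Trait from a lambda-transformed Brownian model.

    Draws one multivariate-normal sample with covariance equal to the BM
    matrix of the tree with off-diagonal entries multiplied by ``lam``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lambda must be in [0, 1]")
    labels, C = tree.bm_covariance()
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    L = np.linalg.cholesky(sigma2 * V)
    rng = substream(seed, "trait-lambda")
    return pd.Series(mean + L @ rng.standard_normal(len(labels)), index=labels)


def _align_elevations(elevations, labels) -> np.ndarray:
    if isinstance(elevations, pd.Series):
        missing = [lab for lab in labels if lab not in elevations.index]
        if missing:
            raise ValueError(f"elevations missing for tips: {missing[:5]}")
        return elevations.reindex(labels).to_numpy(float)
    elev = np.asarray(elevations, float)
    if elev.shape != (len(labels),):
        raise ValueError(
            f"elevations length {elev.size} does not match {len(labels)} tips"
        )
    return elev


# ---------------------------------------------------------------------------
# assay records
# ---------------------------------------------------------------------------


def discretize_ct(true_ct, protocol: AssayParams, direction: str) -> np.ndarray:
    """Project true thresholds onto the assay temperature grid.

    For CT_max the insect is first observed immobile at the smallest grid
    temperature at or above its true threshold (ceiling); for CT_min at the
    largest grid temperature at or below it (floor).  The grid is anchored
    at the protocol start temperature.
    """
    t = np.asarray(true_ct, float)
    k = (t - protocol.start_temp) / protocol.step
    if direction == "ctmax":
        steps = np.ceil(k - 1e-9)
    elif direction == "ctmin":
        steps = -np.ceil(-k - 1e-9)
    else:
        raise ValueError("direction must be 'ctmax' or 'ctmin'")
    return protocol.start_temp + protocol.step * steps


def simulate_assay_records(
    true_ct,
    protocol: AssayParams,
    direction: str,
    seed: int = 0,
    meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Assay table with grid-discretized CT values.

    ``true_ct`` may be a Series (index = individual ids) or an array.
    ``meta`` supplies additional per-individual columns (same length/order).
    """
    if isinstance(true_ct, pd.Series):
        ids = list(true_ct.index)
        values = true_ct.to_numpy(float)
    else:
        values = np.asarray(true_ct, float)
        ids = [f"ind_{i + 1}" for i in range(values.size)]
    df = pd.DataFrame(
        {
            "individual_id": ids,
            "direction": direction,
            "ct_value": discretize_ct(values, protocol, direction),
        }
    )
    if meta is not None:
        meta = meta.reset_index(drop=True)
        for col in meta.columns:
            df[col] = meta[col].to_numpy()
    return df


def simulate_shock_experiment(
    mu_control: float,
    effect: float,
    sd: float,
    n_per_group: int,
    direction: str = "ctmax",
    protocol: AssayParams | None = None,
    elevation: float = 300.0,
    region: str = "neotropics",
    plot_id: str = "P01",
    seed: int = 0,
) -> pd.DataFrame:
    """Two-group hardening experiment with a known tolerance shift.

    ``effect`` follows the tolerance convention: positive means the shocked
    group tolerates more (higher CT_max, or lower CT_min).  Both groups are
    run through the assay grid.
    """
    protocol = protocol or AssayParams()
    rng = substream(seed, "shock")
    shift = effect if direction == "ctmax" else -effect
    control = rng.normal(mu_control, sd, n_per_group)
    shocked = rng.normal(mu_control + shift, sd, n_per_group)
    true_ct = np.concatenate([control, shocked])
    meta = pd.DataFrame(
        {
            "shocked": ["no"] * n_per_group + ["yes"] * n_per_group,
            "elevation": elevation,
            "region": region,
            "plot_id": plot_id,
            "otu_id": "OTU_synth",
            "family": "Fsynth",
            "order": "Osynth",
            "observer": "obs1",
        }
    )
    return simulate_assay_records(true_ct, protocol, direction, meta=meta)


def simulate_community_assays(
    plots: pd.DataFrame,
    slope_per_mat: float,
    intercept: float,
    sd: float,
    n_per_plot: int,
    direction: str = "ctmax",
    protocol: AssayParams | None = None,
    seed: int = 0,
    discretize: bool = True,
) -> pd.DataFrame:
    """Per-plot assay records with a known CT-vs-MAT generative slope.

    ``plots`` needs columns ``plot_id``, ``elevation`` and ``mat`` (mean
    annual temperature, degC).  True CT = intercept + slope * MAT + noise.
    """
    protocol = protocol or AssayParams()
    rng = substream(seed, "community")
    frames = []
    for _, row in plots.iterrows():
        true_ct = intercept + slope_per_mat * row["mat"] + rng.normal(0, sd, n_per_plot)
        ct = discretize_ct(true_ct, protocol, direction) if discretize else true_ct
        frames.append(
            pd.DataFrame(
                {
                    "individual_id": [
                        f"{row['plot_id']}_i{j + 1}" for j in range(n_per_plot)
                    ],
                    "plot_id": row["plot_id"],
                    "elevation": row["elevation"],
                    "mat": row["mat"],
                    "direction": direction,
                    "shocked": "no",
                    "ct_value": ct,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# microclimate
# ---------------------------------------------------------------------------

_SAMPLES_PER_DAY = 96  # 15-min cadence
_SEASON_DAYS = 365


def simulate_microclimate(
    elevation: float,
    params: ClimateParams,
    n_days: int,
    seed: int = 0,
    plot_id: str = "P01",
    kind: str = "air15cm",
    start: str = "2023-01-01T00:00:00+00:00",
) -> TemperatureSeries:
    """Diurnal + seasonal series at 15-min cadence with AR(1) noise.

    value = sea_level_mean - lapse*elevation
            + A_d * sin(diurnal phase)   (peak at 14:00, trough at 02:00)
            + A_s * sin(annual phase)    (365-day period)
            + AR(1) noise with marginal sd ``noise_sd``.
    """
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    n = n_days * _SAMPLES_PER_DAY
    k = np.arange(n)
    level = params.sea_level_mean - params.lapse_per_m * elevation
    diurnal = params.diurnal_amplitude * np.sin(
        2 * np.pi * (k - 32) / _SAMPLES_PER_DAY
    )
    seasonal = params.seasonal_amplitude * np.sin(
        2 * np.pi * k / (_SAMPLES_PER_DAY * _SEASON_DAYS)
    )
    noise = np.zeros(n)
    if params.noise_sd > 0:
        rng = substream(seed, f"climate-{plot_id}-{kind}")
        innov_sd = params.noise_sd * np.sqrt(1 - params.ar1**2)
        eps = rng.normal(0.0, innov_sd, n)
        noise[0] = rng.normal(0.0, params.noise_sd)
        for i in range(1, n):
            noise[i] = params.ar1 * noise[i - 1] + eps[i]
    timestamps = pd.date_range(start=start, periods=n, freq="15min")
    return TemperatureSeries(
        plot_id=plot_id,
        timestamps=timestamps,
        values=level + diurnal + seasonal + noise,
        kind=kind,
        qc=np.full(n, "0b00"),
    )


# ---------------------------------------------------------------------------
# knockdown times
# ---------------------------------------------------------------------------


def simulate_static_knockdowns(
    tdt_truth: TDTParams,
    temps,
    n_per_temp: int = 1,
    noise_sd_log10: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Constant-temperature knockdown times from the TDT law.

    log10(time) = (T_L - T) / z + log10(t_ref) + Gaussian noise.
    """
    temps = np.repeat(np.asarray(temps, float), n_per_temp)
    log_t = (tdt_truth.t_l - temps) / tdt_truth.z + np.log10(tdt_truth.t_ref)
    if noise_sd_log10 > 0:
        rng = substream(seed, "knockdown")
        log_t = log_t + rng.normal(0.0, noise_sd_log10, temps.size)
    return pd.DataFrame({"temp_c": temps, "time_min": 10.0**log_t})


# ---------------------------------------------------------------------------
# protein melting temperatures
# ---------------------------------------------------------------------------


def simulate_tm_table(
    families,
    n_species_per_family: int = 3,
    n_proteins: int = 200,
    grand_mean: float = 46.9,
    order_sd: float = 1.0,
    family_sd: float = 1.0,
    species_sd: float = 0.5,
    protein_sd: float = 3.0,
    orders=None,
    family_shift: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Family-structured protein T_m table (degC).

    T_m = grand_mean + order effect + family effect + species effect +
    protein-level noise; ``family_shift`` adds fixed offsets for chosen
    families (useful for equivariance checks).
    """
    rng = substream(seed, "tm")
    families = list(families)
    if orders is None:
        orders = {fam: f"O{(i % 3) + 1}" for i, fam in enumerate(families)}
    order_names = sorted(set(orders.values()))
    order_eff = dict(zip(order_names, rng.normal(0, order_sd, len(order_names))))
    rows = []
    for fam in families:
        f_eff = rng.normal(0, family_sd) + (family_shift or {}).get(fam, 0.0)
        for s in range(n_species_per_family):
            sp = f"{fam}_sp{s + 1}"
            s_eff = rng.normal(0, species_sd)
            tms = (
                grand_mean
                + order_eff[orders[fam]]
                + f_eff
                + s_eff
                + rng.normal(0, protein_sd, n_proteins)
            )
            rows.append(
                pd.DataFrame(
                    {
                        "species_id": sp,
                        "family": fam,
                        "order": orders[fam],
                        "protein_id": [f"{sp}_p{j + 1}" for j in range(n_proteins)],
                        "tm": tms,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# bundle generation
# ---------------------------------------------------------------------------


def generate_all(config: SimConfig, outdir) -> dict:
    """Write every synthetic input the pipeline consumes, plus the truth.

    Produces ``tree.nwk``, ``assays.csv``, ``plots.csv``,
    ``microclimate.csv``, ``knockdowns.csv``, ``tm_table.csv`` and
    ``truth.json`` under ``outdir`` and returns the objects in memory.
    """
    from pathlib import Path

    from . import io as tio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    tree = simulate_tree(cfg.n_tips, cfg.seed, depth=cfg.tree_depth,
                         n_families=cfg.n_families)
    labels = tree.tip_labels
    rng = substream(cfg.seed, "design")
    grid = np.asarray(cfg.elevation_grid, float)
    plot_ids = [f"P{i + 1:02d}" for i in range(grid.size)]
    tip_plot = rng.integers(grid.size, size=len(labels))
    elevations = pd.Series(grid[tip_plot], index=labels)

    trait = simulate_trait_ou(tree, cfg.trait_params, elevations, cfg.seed)
    noise = substream(cfg.seed, "within-species")
    true_ind = trait + noise.normal(0, cfg.within_species_sd, len(labels))
    meta = pd.DataFrame(
        {
            "otu_id": labels,
            "family": [tree.family.get(t, "F01") for t in labels],
            "order": [tree.order.get(t, "O1") for t in labels],
            "region": "neotropics",
            "plot_id": [plot_ids[i] for i in tip_plot],
            "elevation": elevations.to_numpy(),
            "shocked": "no",
            "observer": "obs1",
        }
    )
    assays = simulate_assay_records(
        pd.Series(true_ind.to_numpy(), index=[f"ind_{i+1}" for i in range(len(labels))]),
        cfg.assay_params,
        "ctmax",
        meta=meta,
    )

    clim = cfg.climate_params
    plots = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "elevation": grid,
            "bio1": clim.sea_level_mean - clim.lapse_per_m * grid,
            "bio5": clim.sea_level_mean - clim.lapse_per_m * grid + 6.0,
            "bio5_ssp126": clim.sea_level_mean - clim.lapse_per_m * grid + 7.5,
            "bio5_ssp370": clim.sea_level_mean - clim.lapse_per_m * grid + 9.5,
            "bio5_ssp585": clim.sea_level_mean - clim.lapse_per_m * grid + 11.0,
        }
    )
    series = [
        simulate_microclimate(e, clim, n_days=30, seed=cfg.seed, plot_id=p)
        for p, e in zip(plot_ids, grid)
    ]
    knockdowns = simulate_static_knockdowns(
        cfg.tdt_truth, np.arange(38.0, 47.0), n_per_temp=3,
        noise_sd_log10=0.05, seed=cfg.seed,
    )
    tm_table = simulate_tm_table(
        sorted(set(tree.family.values())), seed=cfg.seed,
        orders={f: tree.order[next(t for t in labels if tree.family[t] == f)]
                for f in set(tree.family.values())},
    )

    tree.write_newick(outdir / "tree.nwk")
    tio.write_table(assays, outdir / "assays.csv", seed=cfg.seed)
    tio.write_table(plots, outdir / "plots.csv", seed=cfg.seed)
    tio.write_series(series, outdir / "microclimate.csv", seed=cfg.seed)
    tio.write_table(knockdowns, outdir / "knockdowns.csv", seed=cfg.seed)
    tio.write_table(tm_table, outdir / "tm_table.csv", seed=cfg.seed)
    truth = {
        "seed": cfg.seed,
        "trait_params": asdict(cfg.trait_params),
        "assay_params": asdict(cfg.assay_params),
        "climate_params": asdict(cfg.climate_params),
        "tdt_truth": {"z": cfg.tdt_truth.z, "t_l": cfg.tdt_truth.t_l,
                      "t_ref": cfg.tdt_truth.t_ref},
        "within_species_sd": cfg.within_species_sd,
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2)
    return {
        "tree": tree,
        "trait": trait,
        "assays": assays,
        "plots": plots,
        "series": series,
        "knockdowns": knockdowns,
        "tm_table": tm_table,
        "truth": truth,
    }
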