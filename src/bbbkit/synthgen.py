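"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator emulates one class of raw data the pipeline consumes:

* Transwell tracer accumulation under draw-and-replace sampling,
  integrated from an explicit two-compartment mass balance so that the
  upper chamber is allowed to deplete (the linear single-compartment
  permeability formula is then only an approximation, which downstream
  estimators can be tested against);
* paired raw/blank TEER readings;
* confocal-like z-stacks: a Voronoi cell mosaic whose borders carry a
  Gaussian-profile junction ridge, and a textured glycocalyx field;
* negative-binomial RNA-seq counts with a uniformly down-regulated
  deletion-region block as the positive control;
* scale-free-like protein-interaction networks with one planted
  high-influence node.

All generators are deterministic given their seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Voronoi

from .datatypes import AssayGeometry, CountMatrix, ImageStack, TranswellSeries

__all__ = [
    "TranswellGroundTruth",
    "ImageGroundTruth",
    "CountsGroundTruth",
    "NetworkGroundTruth",
    "gen_transwell_series",
    "gen_teer_readings",
    "gen_junction_stack",
    "gen_esg_stack",
    "gen_counts",
    "gen_network",
]


# ---------------------------------------------------------------------------
# ground-truth parameter records


@dataclass(frozen=True)
class TranswellGroundTruth:
    """True permeability and measurement noise for a simulated run."""

    p_true_cm_s: float = 3.8e-6
    noise_sd_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_true_cm_s < 0:
            raise ValueError("p_true_cm_s must be non-negative")
        if self.noise_sd_um < 0:
            raise ValueError("noise_sd_um must be non-negative")


@dataclass(frozen=True)
class ImageGroundTruth:
    """Ground truth for a synthetic junction or glycocalyx stack.

    ``deficit_factor`` scales the signal above background; 1.0 is the
    control condition, values below 1 emulate the patient deficit.
    """

    junction_amplitude: float = 100.0
    background_level: float = 10.0
    deficit_factor: float = 1.0
    cell_count: int = 20
    pixel_size_um: float = 0.25
    noise_sd: float = 0.0
    seed: int = 0
    field_px: int = 256
    n_slices: int = 5
    ridge_fwhm_um: float = 1.0

    def __post_init__(self) -> None:
        if not 0 < self.deficit_factor <= 1:
            raise ValueError("deficit_factor must be in (0, 1]")
        if self.junction_amplitude <= 0:
            raise ValueError("junction_amplitude must be positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass(frozen=True)
class CountsGroundTruth:
    """Ground truth for a synthetic gene x sample count matrix.

    The deletion block is uniformly scaled by ``deletion_fc`` in the DEL
    group (0.5 = hemizygous loss). A deterministic ``round(de_fraction *
    n_other)`` of the remaining genes get a true effect whose |log2 FC|
    is log-normal with median ``de_log2fc_median`` and spread
    ``de_log2fc_sigma`` (sigma 0 gives a fixed magnitude); ``de_up_share``
    of them are up-regulated.
    """

    n_genes: int = 2000
    n_per_group: int = 3
    deletion_gene_ids: tuple[str, ...] = ()
    deletion_fc: float = 0.5
    de_fraction: float = 0.1
    dispersion: float = 0.05
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    seed: int = 0
    de_up_share: float = 0.5
    de_log2fc_median: float = 1.0
    de_log2fc_sigma: float = 0.5
    base_mean_log: float = float(np.log(200.0))
    base_sigma_log: float = 1.3
    deletion_mean_log: float = float(np.log(500.0))
    deletion_sigma_log: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.deletion_fc < 1:
            raise ValueError("deletion_fc must be in (0, 1)")
        if not 0 <= self.de_fraction < 1:
            raise ValueError("de_fraction must be in [0, 1)")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if len(set(self.deletion_gene_ids)) != len(self.deletion_gene_ids):
            raise ValueError("deletion gene ids must be unique")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")


@dataclass(frozen=True)
class NetworkGroundTruth:
    """Ground truth for a synthetic interaction network."""

    n_nodes: int = 80
    attachment_model: str = "planted_hub"
    hub_id: str = "HUB"
    seed: int = 0
    n_deletion: int = 5
    deletion_log2fc: float = -1.0
    hub_in_deletion: bool = True

    def __post_init__(self) -> None:
        if self.attachment_model not in ("planted_hub", "preferential_attachment"):
            raise ValueError("unknown attachment_model")
        if self.n_nodes < 4:
            raise ValueError("n_nodes must be at least 4")


# ---------------------------------------------------------------------------
# Transwell assay


def gen_transwell_series(geom: AssayGeometry,
                         truth: TranswellGroundTruth) -> TranswellSeries:
    """Simulate draw-and-replace sampling of lower-chamber tracer.

    The two-compartment mass balance dM/dt = P*S*(C_U - C_L) is integrated
    with explicit sub-stepping (<= 1 s), transferring identical mass
    increments between chambers so that tracer mass is conserved exactly.
    Draws are instantaneous and perfectly mixed: the recorded value is the
    pre-draw lower concentration, after which the lower chamber is diluted
    by (V_L - V_s)/V_L. Gaussian measurement noise is applied to the
    recorded values only, never to the physical state.
    """
    rng = np.random.default_rng(truth.seed)
    p, s_area = truth.p_true_cm_s, geom.membrane_area_cm2
    v_up, v_lo = geom.upper_volume_ml, geom.lower_volume_ml
    v_draw = geom.sample_volume_ml
    c_up, c_lo = geom.upper_conc_um, 0.0

    n_intervals = int(round(geom.duration_min / geom.sample_interval_min))
    times = np.arange(n_intervals + 1) * geom.sample_interval_min
    interval_s = geom.sample_interval_min * 60.0
    n_sub = max(1, int(np.ceil(interval_s)))  # sub-steps of <= 1 s
    dt = interval_s / n_sub

    recorded = [c_lo]
    for _ in range(n_intervals):
        for _ in range(n_sub):
            dm = p * s_area * (c_up - c_lo) * dt
            c_up -= dm / v_up
            c_lo += dm / v_lo
        recorded.append(c_lo)
        c_lo *= (v_lo - v_draw) / v_lo  # draw-and-replace dilution

    measured = np.asarray(recorded)
    if truth.noise_sd_um > 0:
        measured = measured + rng.normal(0.0, truth.noise_sd_um, measured.shape)
    measured = np.clip(measured, 0.0, None)

    gt = {"p_true_cm_s": truth.p_true_cm_s, "noise_sd_um": truth.noise_sd_um,
          "seed": truth.seed}
    return TranswellSeries(times, measured, geom, ground_truth=gt)


def transwell_mass_balance(geom: AssayGeometry,
                           truth: TranswellGroundTruth) -> dict[str, float]:
    """Noise-free tracer bookkeeping for the simulated protocol.

    Returns final upper/lower masses and total withdrawn mass (uM * mL)
    alongside the initial mass, for conservation checks.
    """
    p, s_area = truth.p_true_cm_s, geom.membrane_area_cm2
    v_up, v_lo, v_draw = geom.upper_volume_ml, geom.lower_volume_ml, geom.sample_volume_ml
    c_up, c_lo, withdrawn = geom.upper_conc_um, 0.0, 0.0
    n_intervals = int(round(geom.duration_min / geom.sample_interval_min))
    interval_s = geom.sample_interval_min * 60.0
    n_sub = max(1, int(np.ceil(interval_s)))
    dt = interval_s / n_sub
    for _ in range(n_intervals):
        for _ in range(n_sub):
            dm = p * s_area * (c_up - c_lo) * dt
            c_up -= dm / v_up
            c_lo += dm / v_lo
        withdrawn += c_lo * v_draw
        c_lo *= (v_lo - v_draw) / v_lo
    return {
        "initial_mass": geom.upper_conc_um * v_up,
        "upper_mass": c_up * v_up,
        "lower_mass": c_lo * v_lo,
        "withdrawn_mass": withdrawn,
    }


def gen_teer_readings(true_resistance_ohm: float, blank_resistance_ohm: float,
                      n: int, noise_sd_ohm: float = 0.0,
                      seed: int = 0) -> pd.DataFrame:
    """Paired (total, blank) raw TEER readings around a true net resistance.

    Independent Gaussian noise is added to both the total (barrier +
    filter) and the blank-filter reading, as in repeated chopstick-
    electrode measurements.
    """
    if true_resistance_ohm <= 0 or blank_resistance_ohm <= 0:
        raise ValueError("resistances must be positive")
    if n < 1:
        raise ValueError("need at least one reading")
    rng = np.random.default_rng(seed)
    total = true_resistance_ohm + blank_resistance_ohm + rng.normal(0, noise_sd_ohm, n)
    blank = blank_resistance_ohm + rng.normal(0, noise_sd_ohm, n)
    return pd.DataFrame({
        "sample_id": [f"rep{i + 1}" for i in range(n)],
        "total_ohm": total,
        "blank_ohm": blank,
    })


# ---------------------------------------------------------------------------
# imaging


def _voronoi_segments(points: np.ndarray, size: float) -> list[tuple[float, float, float, float]]:
    """Finite Voronoi ridge segments between the given points, clipped to
    the [0, size] x [0, size] box.

    The point set is mirrored across all four box edges so every ridge
    between two original points is finite and geometrically exact inside
    the box.
    """
    mirrored = [points]
    for axis in (0, 1):
        for edge in (0.0, size):
            m = points.copy()
            m[:, axis] = 2 * edge - m[:, axis]
            mirrored.append(m)
    vor = Voronoi(np.vstack(mirrored))
    n = len(points)
    segments = []
    for (p1, p2), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if p1 >= n and p2 >= n:
            continue
        if -1 in verts:
            continue
        (x0, y0), (x1, y1) = vor.vertices[verts]
        seg = _clip_segment(x0, y0, x1, y1, size)
        if seg is not None and p1 < n and p2 < n:
            segments.append(seg)
    return segments


def _clip_segment(x0, y0, x1, y1, size):
    """Liang-Barsky clipping of a segment to the [0, size]^2 box."""
    dx, dy = x1 - x0, y1 - y0
    t0, t1 = 0.0, 1.0
    for p, q in ((-dx, x0), (dx, size - x0), (-dy, y0), (dy, size - y0)):
        if p == 0:
            if q < 0:
                return None
            continue
        r = q / p
        if p < 0:
            if r > t1:
                return None
            t0 = max(t0, r)
        else:
            if r < t0:
                return None
            t1 = min(t1, r)
    if t1 <= t0:
        return None
    return (x0 + t0 * dx, y0 + t0 * dy, x0 + t1 * dx, y0 + t1 * dy)


def _segment_distance_field(segments, shape) -> np.ndarray:
    """Euclidean distance (px) from every pixel centre to the nearest segment."""
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    pts = np.stack([xs.ravel(), ys.ravel()], axis=1).astype(float)
    dmin = np.full(pts.shape[0], np.inf)
    for (x0, y0, x1, y1) in segments:
        d = np.array([x1 - x0, y1 - y0])
        L2 = d @ d
        rel = pts - np.array([x0, y0])
        t = np.clip(rel @ d / L2, 0.0, 1.0) if L2 > 0 else np.zeros(len(pts))
        proj = np.stack([x0 + t * d[0], y0 + t * d[1]], axis=1)
        dist = np.linalg.norm(pts - proj, axis=1)
        np.minimum(dmin, dist, out=dmin)
    return dmin.reshape(h, w)


#: half-width (px) of the flat crest at the top of each ridge; models the
#: finite rasterisation of a sub-resolution junction and guarantees that
#: pixels on the border attain exactly background + amplitude * deficit.
_CREST_HALF_WIDTH_PX = 1.5

#: relative z-envelope of the junction signal through the stack (peak 1.0
#: at the mid-slice, emulating focus through the junctional plane).
def _z_envelope(n_slices: int) -> np.ndarray:
    z = np.arange(n_slices) - (n_slices - 1) / 2
    env = np.exp(-(z ** 2) / (2 * max(n_slices / 3.0, 1.0) ** 2))
    return env / env.max()


def gen_junction_stack(truth: ImageGroundTruth) -> tuple[ImageStack, list[tuple[float, float, float, float]]]:
    """Voronoi cell mosaic with junction borders rendered as ridges.

    Each cell-cell border carries a ridge with a Gaussian cross-section
    (FWHM ``ridge_fwhm_um``) whose crest sits ``junction_amplitude *
    deficit_factor`` above ``background_level``. Returns the stack and the
    ground-truth border segments (x0, y0, x1, y1 in pixel coordinates)
    for profile sampling.
    """
    if truth.cell_count < 2:
        raise ValueError("need at least 2 cells to form a junction")
    rng = np.random.default_rng(truth.seed)
    size = float(truth.field_px)
    # rejection-free jittered grid keeps cells from degenerating
    pts = rng.uniform(0.05 * size, 0.95 * size, size=(truth.cell_count, 2))
    segments = _voronoi_segments(pts, size)
    segments = [s for s in segments if np.hypot(s[2] - s[0], s[3] - s[1]) >= 2.0]

    dist_px = _segment_distance_field(segments, (truth.field_px, truth.field_px))
    sigma_px = (truth.ridge_fwhm_um / 2.354820045) / truth.pixel_size_um
    shoulder = np.clip(dist_px - _CREST_HALF_WIDTH_PX, 0.0, None)
    ridge = np.exp(-shoulder ** 2 / (2 * sigma_px ** 2))
    plane = truth.background_level + truth.junction_amplitude * truth.deficit_factor * ridge

    env = _z_envelope(truth.n_slices)
    stack = truth.background_level + env[:, None, None] * (plane - truth.background_level)
    if truth.noise_sd > 0:
        stack = stack + rng.normal(0.0, truth.noise_sd, stack.shape)
    stack = np.clip(stack, 0.0, None)
    return ImageStack(stack, truth.pixel_size_um, channel="junction"), segments


def gen_esg_stack(truth: ImageGroundTruth) -> ImageStack:
    """Spatially textured glycocalyx-like field.

    The in-focus signal is ``background_level`` plus a smooth texture
    whose spatial mean is exactly ``junction_amplitude * deficit_factor``
    (the texture is mean-centred before scaling), so the field-mean
    statistic recovers the planted deficit without bias. The same pattern
    fills every slice; voxel noise is independent.
    """
    if truth.cell_count < 2:
        raise ValueError("need at least 2 cells")
    rng = np.random.default_rng(truth.seed)
    n = truth.field_px
    raw = ndimage.gaussian_filter(rng.normal(size=(n, n)), sigma=n / 40.0)
    raw -= raw.mean()
    peak = np.abs(raw).max()
    texture = raw / peak if peak > 0 else raw
    mean_level = truth.junction_amplitude * truth.deficit_factor
    plane = truth.background_level + mean_level * (1.0 + 0.4 * texture)
    stack = np.repeat(plane[None, :, :], max(1, truth.n_slices), axis=0)
    if truth.noise_sd > 0:
        stack = stack + rng.normal(0.0, truth.noise_sd, stack.shape)
    stack = np.clip(stack, 0.0, None)
    return ImageStack(stack, truth.pixel_size_um, z_step_um=0.32, channel="esg")


# ---------------------------------------------------------------------------
# counts


def gen_counts(truth: CountsGroundTruth) -> CountMatrix:
    """Negative-binomial counts with a down-scaled deletion-region block.

    Per-gene baseline means are log-normal; deletion genes are drawn from
    a higher, tighter distribution (the positive controls are
    well-expressed genes). DEL-group means are the baseline times the
    gene's true fold change; library-size factors are uniform in
    ``lib_size_range``. Counts are NB with a single dispersion parameter
    (var = mu + dispersion * mu^2).
    """
    rng = np.random.default_rng(truth.seed)
    n_del = len(truth.deletion_gene_ids)
    if n_del > truth.n_genes:
        raise ValueError("more deletion genes than genes")
    n_other = truth.n_genes - n_del

    gene_ids = list(truth.deletion_gene_ids) + [f"G{i:05d}" for i in range(n_other)]
    base = np.empty(truth.n_genes)
    base[:n_del] = rng.lognormal(truth.deletion_mean_log, truth.deletion_sigma_log, n_del)
    base[n_del:] = rng.lognormal(truth.base_mean_log, truth.base_sigma_log, n_other)

    log2fc = np.zeros(truth.n_genes)
    log2fc[:n_del] = np.log2(truth.deletion_fc)
    n_de = int(round(truth.de_fraction * n_other))
    de_idx = np.array([], dtype=int)
    if n_de:
        de_idx = n_del + rng.choice(n_other, n_de, replace=False)
        mag = rng.lognormal(np.log(truth.de_log2fc_median), truth.de_log2fc_sigma, n_de)
        n_up = int(round(truth.de_up_share * n_de))
        signs = np.concatenate([np.ones(n_up), -np.ones(n_de - n_up)])
        log2fc[de_idx] = signs * mag

    n = truth.n_per_group
    lib = rng.uniform(*truth.lib_size_range, size=2 * n)
    mu = base[:, None] * lib[None, :]
    mu[:, n:] = mu[:, n:] * 2.0 ** log2fc[:, None]
    r = 1.0 / truth.dispersion
    counts = rng.negative_binomial(r, r / (r + mu))

    sample_ids = [f"WT_{i + 1}" for i in range(n)] + [f"DEL_{i + 1}" for i in range(n)]
    df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    groups = {c: ("WT" if c.startswith("WT") else "DEL") for c in sample_ids}
    is_de = np.zeros(truth.n_genes, dtype=bool)
    is_de[de_idx] = True
    truth_df = pd.DataFrame({
        "true_log2fc": log2fc,
        "is_de": is_de,
        "in_deletion": [i < n_del for i in range(truth.n_genes)],
        "base_mean_true": base,
        "lib_factor_mean": np.full(truth.n_genes, lib.mean()),
    }, index=gene_ids)
    return CountMatrix(df, groups, truth=truth_df)


# ---------------------------------------------------------------------------
# networks


def gen_network(truth: NetworkGroundTruth):
    """Scale-free-like interaction network, optionally with a planted hub.

    ``planted_hub``: a Barabasi-Albert base graph plus extra edges from
    the hub until its degree is both maximal and at least 3x the median
    degree. Node attributes carry an expression log2 fold change and a
    deletion-region flag (the hub is flagged when ``hub_in_deletion``).
    """
    import networkx as nx

    from .network_topology import InfluenceNetwork

    rng = np.random.default_rng(truth.seed)
    n = truth.n_nodes
    g = nx.barabasi_albert_graph(n, 2, seed=int(rng.integers(2 ** 31)))
    names = {i: f"G{i:03d}" for i in range(n)}

    hub_node = None
    if truth.attachment_model == "planted_hub":
        hub_node = int(np.argmax([g.degree(i) for i in range(n)]))
        names[hub_node] = truth.hub_id
        # the hub must be the unambiguous high-influence node, well clear
        # of the natural scale-free hubs: at least 3x the median degree,
        # 1.5x the largest base-graph degree, and 0.4n
        degrees = np.array([g.degree(i) for i in range(n)])
        target = max(int(np.ceil(3 * np.median(degrees))) + 1,
                     int(np.ceil(1.5 * degrees.max())), int(np.ceil(0.4 * n)))
        others = [i for i in range(n) if i != hub_node and not g.has_edge(hub_node, i)]
        rng.shuffle(others)
        for j in others:
            if g.degree(hub_node) >= target:
                break
            g.add_edge(hub_node, j)

    g = nx.relabel_nodes(g, names)
    log2fc = {v: float(rng.normal(0.0, 1.0)) for v in g.nodes}
    in_del = {v: False for v in g.nodes}
    non_hub = sorted(v for v in g.nodes if v != truth.hub_id)
    n_extra = max(0, truth.n_deletion - (1 if truth.hub_in_deletion and hub_node is not None else 0))
    for v in rng.choice(non_hub, size=min(n_extra, len(non_hub)), replace=False):
        in_del[v] = True
        log2fc[v] = truth.deletion_log2fc + float(rng.normal(0.0, 0.2))
    if hub_node is not None and truth.hub_in_deletion:
        in_del[truth.hub_id] = True
        log2fc[truth.hub_id] = truth.deletion_log2fc + float(rng.normal(0.0, 0.2))

    nx.set_node_attributes(g, log2fc, "log2fc")
    nx.set_node_attributes(g, in_del, "in_deletion")
    return InfluenceNetwork(g)
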