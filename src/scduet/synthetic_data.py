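"""Synthetic multiplexed plates with known ground truth.

Emulates the experimental design this pipeline targets: plate-based picking of leaf
protoplasts into 96-well plates collected on two days, with empty wells and
cell doublets; an abundant epidermis split into two metabolic subtypes (one
accumulating a secologanin-like iridoid alone, one additionally accumulating a
mauritianin-like flavonoid); rare idioblasts storing alkaloid pools reaching
millimolar levels; a very rare IPAP type (<4 % of cells) expressing early
iridoid genes; and parenchyma. Metabolite pools are cell-type specific and
log-normal, spanning the µM-mM range. Two analytes are deliberately decoupled
from their biosynthesis genes by transport: a catharanthine-like alkaloid made
in the epidermis but stored in idioblasts (with a low ubiquitous pool, as
transported metabolites are detected broadly), and a loganic-acid-like iridoid
made in IPAP cells but stored in parenchyma.

The lysate-split forward model applied here (half the cell content, diluted
into the analysis aliquot, converted to a peak area through a linear response)
is exactly what :mod:`scduet.ms_quant` inverts, so with zero noise the
quantify stage recovers the simulated concentrations identically.

Counts are negative binomial with a shared dispersion and log-normal library
sizes. Marker and biosynthesis genes have mean zero outside their cell type;
biosynthesis genes of in-situ analytes follow a unimodal link
``g(c) = a * log10(1 + c/c0) * exp(-c/c1)`` of their analyte's concentration,
rising with concentration and declining slightly past ~100 mM.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import (
    ConfigError,
    ExpressionSet,
    MetaboliteMatrix,
    WellRecord,
    WellStatus,
    log,
)

CELL_TYPES = ["epidermis_A", "epidermis_B", "idioblast", "ipap", "parenchyma"]

EPIDERMIS = ("epidermis_A", "epidermis_B")


@dataclass
class AnalyteSpec:
    """One targeted analyte: role, biosynthesis genes and where they are
    expressed, cell-type concentration pools (log10 µM mean, log10 sd), an
    optional ubiquitous background pool, and an empty-well trace rate."""

    name: str
    role: str  # in_situ | transported | ubiquitous
    genes: tuple[str, ...]
    expressed_in: tuple[str, ...]
    pools: dict[str, tuple[float, float]]
    background: tuple[float, float] | None = None
    trace_empty_rate: float = 0.0
    # fraction of the in-type expression level its genes keep outside
    # `expressed_in` (transported-analyte pathway genes are detectable at low
    # levels across cell types; marker genes must keep this at 0)
    gene_leak: float = 0.0


def default_analytes() -> list[AnalyteSpec]:
    """Twelve analytes shaped like a targeted alkaloid/iridoid/flavonoid panel."""
    idio_late = ("NMT", "D4H", "DAT")       # late alkaloid pathway, idioblast
    idio_het = ("THAS", "HYS", "GS1")       # heteroyohimbine branch, idioblast
    seco = ("LAMT", "SLS", "SGD")           # seco-iridoid pathway, epidermis
    cath = ("CS", "DPAS", "PAS")            # catharanthine branch, epidermis
    flav = ("CHS", "C4H", "FLS")            # flavonoid pathway, epidermis_B
    irid = ("G8H", "ISY", "IO")             # early iridoid pathway, IPAP
    return [
        AnalyteSpec("secologanin", "in_situ", seco, EPIDERMIS,
                    {"epidermis_A": (2.5, 0.4), "epidermis_B": (2.5, 0.4)}),
        AnalyteSpec("mauritianin", "in_situ", flav, ("epidermis_B",),
                    {"epidermis_B": (2.0, 0.4)}),
        AnalyteSpec("vindoline", "in_situ", idio_late, ("idioblast",),
                    {"idioblast": (4.0, 0.5)}, trace_empty_rate=0.05),
        AnalyteSpec("deacetylvindoline", "in_situ", idio_late, ("idioblast",),
                    {"idioblast": (1.0, 0.4)}),
        AnalyteSpec("anhydrovinblastine", "in_situ", idio_late, ("idioblast",),
                    {"idioblast": (1.5, 0.4)}),
        AnalyteSpec("vindorosine", "in_situ", idio_late, ("idioblast",),
                    {"idioblast": (1.5, 0.4)}),
        AnalyteSpec("serpentine", "in_situ", idio_het, ("idioblast",),
                    {"idioblast": (2.0, 0.4)}),
        AnalyteSpec("ajmalicine", "in_situ", idio_het, ("idioblast",),
                    {"idioblast": (1.2, 0.4)}),
        AnalyteSpec("vindolinine", "in_situ", idio_het, ("idioblast",),
                    {"idioblast": (1.3, 0.4)}),
        AnalyteSpec("catharanthine", "transported", cath, EPIDERMIS,
                    {"idioblast": (3.0, 0.4)}, background=(0.8, 0.3), gene_leak=0.15),
        AnalyteSpec("loganic_acid", "transported", irid, ("ipap",),
                    {"parenchyma": (4.6, 0.4)}, trace_empty_rate=0.05),
        AnalyteSpec("strictosidine", "ubiquitous", ("TDC", "STR"), EPIDERMIS,
                    {}, background=(0.5, 0.3)),
    ]


# cell-type-restricted genes that are not biosynthesis genes of any analyte
MARKER_ONLY_GENES = {"NLTP2": EPIDERMIS, "MATE1": ("idioblast",)}
# epidermis_B-enriched genes (expressed in both subtypes, 4x higher in B)
DE_GENES_B_UP = ("KCS", "LTP1", "LTP2")
N_GENERIC_TRANSPORTERS = 28


@dataclass
class SimulationConfig:
    """Study-shaped defaults: four 96-well plates collected on two days,
    2,000 genes, 12 analytes, ~24 % empty wells and ~3 % doublets."""

    n_plates: int = 4
    wells_per_plate: int = 96
    frac_empty: float = 0.24
    frac_doublet: float = 0.03
    cell_type_props: dict[str, float] = field(
        default_factory=lambda: {
            "epidermis_A": 0.30,
            "epidermis_B": 0.22,
            "idioblast": 0.09,
            "ipap": 0.03,
            "parenchyma": 0.36,
        }
    )
    n_genes: int = 2000
    analytes: list[AnalyteSpec] = field(default_factory=default_analytes)
    # each cell type over-expresses a broad program of otherwise generic
    # genes, as real cell types do, so that unsupervised structure does not
    # hinge on the handful of exclusive markers
    type_program_genes: int = 60
    type_program_fold: float = 3.0
    nb_dispersion: float = 2.0
    depth_mean: float = 10000.0
    depth_log_sd: float = 0.7
    gene_weight_log_sd: float = 1.8
    special_gene_weight: float = 3.0
    diameter_range_um: tuple[float, float] = (30.0, 50.0)
    # unimodal link g(c) = a*log10(1 + c/c0)*exp(-c/c1); peak near 100 mM
    trend_a: float = 1.0
    trend_c0_uM: float = 100.0
    trend_c1_uM: float = 5.0e5
    # shared within-cell latent: correlation of log10 pools in the same cell
    pool_latent_weight: float = 0.7
    # calibration chemistry
    calib_ladder_uM: tuple[float, float] = (1e-6, 1e-4)
    calib_points: int = 5
    calib_replicates: int = 3
    calib_slope_log10_mean: float = 5.0
    calib_slope_log10_sd: float = 0.2
    calib_intercept: float = 0.0
    calib_cv: float = 0.05
    instrument_floor_uM: float = 3e-7  # analysis-solution conc below which area = 0
    trace_analysis_conc_uM: float = 5e-6
    aliquot_volume_uL: float = 4.0  # must match PipelineConfig.aliquot_volume_uL
    # gene-level biology (relative expression levels, transcript lengths) is a
    # property of the organism, fixed across experiments; `seed` varies only
    # the sampling (wells, cells, noise)
    gene_profile_seed: int = 20231
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.cell_type_props.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"cell_type_props must sum to 1, got {total}")
        if not set(self.cell_type_props) <= set(CELL_TYPES):
            raise ConfigError(f"unknown cell types: {set(self.cell_type_props) - set(CELL_TYPES)}")
        if self.frac_empty < 0 or self.frac_doublet < 0 or self.frac_empty + self.frac_doublet > 1:
            raise ConfigError("frac_empty/frac_doublet must be proportions with sum <= 1")
        for spec in self.analytes:
            for mu, sd in spec.pools.values():
                if sd < 0:
                    raise ConfigError(f"{spec.name}: pool sd must be >= 0")
            if spec.background is not None and spec.background[1] < 0:
                raise ConfigError(f"{spec.name}: background sd must be >= 0")
        if int(self.seed) != self.seed:
            raise ConfigError("seed must be an integer")
        self.seed = int(self.seed)

    # --- derived gene universe -------------------------------------------
    def special_genes(self) -> dict[str, tuple[str, ...]]:
        """Map of every cell-type-restricted gene to its expressing types."""
        out: dict[str, tuple[str, ...]] = {}
        for spec in self.analytes:
            for g in spec.genes:
                out.setdefault(g, spec.expressed_in)
        out.update(MARKER_ONLY_GENES)
        return out

    def transporter_genes(self) -> list[str]:
        generic = [f"TRANS{i:02d}" for i in range(1, N_GENERIC_TRANSPORTERS + 1)]
        return ["NPF2.4", "MATE1"] + generic

    def gene_list(self) -> list[str]:
        named = list(self.special_genes())
        named += [g for g in DE_GENES_B_UP]
        named += [g for g in self.transporter_genes() if g not in named]
        if len(named) > self.n_genes:
            raise ConfigError("n_genes too small for the named gene set")
        generic = [f"G{i:04d}" for i in range(1, self.n_genes - len(named) + 1)]
        return named + generic

    def marker_map(self) -> dict[str, list[str]]:
        return {
            "idioblast": ["D4H", "DAT"],
            "ipap": ["G8H", "ISY"],
            "epidermis_A": ["NLTP2"],
            "epidermis_B": ["NLTP2"],
        }


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated experiment, for parameter-recovery tests."""

    type_of_well: dict[str, str]                      # empty wells -> "none"
    doublet_components: dict[str, tuple[str, str]]
    biosynthesis_genes: dict[str, tuple[str, ...]]
    role_of_analyte: dict[str, str]
    marker_map: dict[str, list[str]]
    de_genes: tuple[str, ...]
    transporters: list[str]
    type_programs: dict[str, list[str]] = field(default_factory=dict)
    conc_true: MetaboliteMatrix | None = None
    doublet_component_counts: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)
    pool_latent: dict[str, float] = field(default_factory=dict)


def _rng(cfg: SimulationConfig, op: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, op)))


def trend_link(c: np.ndarray | float, cfg: SimulationConfig) -> np.ndarray | float:
    """Unimodal expression-vs-concentration link g(c)."""
    c = np.asarray(c, dtype=float)
    return cfg.trend_a * np.log10(1.0 + c / cfg.trend_c0_uM) * np.exp(-c / cfg.trend_c1_uM)


def trend_peak_uM(cfg: SimulationConfig) -> float:
    """Numeric argmax of the link, on a dense log grid."""
    grid = np.logspace(0, 7, 20000)
    return float(grid[np.argmax(trend_link(grid, cfg))])


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def simulate_wells(cfg: SimulationConfig) -> tuple[list[WellRecord], SyntheticTruth]:
    """Draw plate layout, picked statuses, diameters and true cell types."""
    rng = _rng(cfg, 1)
    rows = "ABCDEFGH"
    types = list(cfg.cell_type_props)
    props = np.array([cfg.cell_type_props[t] for t in types])
    p_status = [1.0 - cfg.frac_empty - cfg.frac_doublet, cfg.frac_doublet, cfg.frac_empty]

    wells: list[WellRecord] = []
    type_of_well: dict[str, str] = {}
    doublets: dict[str, tuple[str, str]] = {}
    latents: dict[str, float] = {}
    lo, hi = cfg.diameter_range_um
    for p in range(1, cfg.n_plates + 1):
        batch = f"day{(p - 1) // 2 + 1}"
        for i in range(cfg.wells_per_plate):
            row, col = rows[(i // 12) % 8], i % 12 + 1
            suffix = "" if cfg.wells_per_plate <= 96 else f"-{i // 96}"
            well_id = f"P{p}-{row}{col:02d}{suffix}"
            status = ["single", "doublet", "empty"][int(rng.choice(3, p=p_status))]
            if status == "empty":
                wells.append(WellRecord(well_id, f"P{p}", batch, WellStatus.EMPTY, None))
                type_of_well[well_id] = "none"
                continue
            diameter = float(rng.uniform(lo, hi))
            wells.append(WellRecord(well_id, f"P{p}", batch, WellStatus(status), diameter))
            latents[well_id] = float(rng.normal())
            if status == "doublet":
                t1, t2 = (types[int(rng.choice(len(types), p=props))] for _ in range(2))
                doublets[well_id] = (t1, t2)
                type_of_well[well_id] = t1
            else:
                type_of_well[well_id] = types[int(rng.choice(len(types), p=props))]

    truth = SyntheticTruth(
        type_of_well=type_of_well,
        doublet_components=doublets,
        biosynthesis_genes={a.name: a.genes for a in cfg.analytes},
        role_of_analyte={a.name: a.role for a in cfg.analytes},
        marker_map=cfg.marker_map(),
        de_genes=DE_GENES_B_UP,
        transporters=cfg.transporter_genes(),
        pool_latent=latents,
    )
    n_status = pd.Series([w.status.value for w in wells]).value_counts().to_dict()
    log.info("simulated %d wells (%s), seed %d", len(wells), n_status, cfg.seed)
    return wells, truth


def simulate_metabolites(truth: SyntheticTruth, cfg: SimulationConfig) -> MetaboliteMatrix:
    """Draw true intracellular concentrations for every well.

    Pools are log-normal per (analyte, cell type) with a shared within-cell
    latent so that alkaloids stored in the same cell co-occur; analytes absent
    from a type are exactly 0; empty wells are all-zero. The matrix is also
    attached to ``truth.conc_true``.
    """
    if not truth.type_of_well:
        raise ConfigError("truth has no wells")
    rng = _rng(cfg, 3)
    wells = list(truth.type_of_well)
    names = [a.name for a in cfg.analytes]
    conc = np.zeros((len(names), len(wells)))
    w_lat = cfg.pool_latent_weight
    resid = math.sqrt(max(1.0 - w_lat**2, 0.0))

    def draw(mu_sd: tuple[float, float], well: str) -> float:
        mu, sd = mu_sd
        z = w_lat * truth.pool_latent.get(well, 0.0) + resid * rng.normal()
        return float(10.0 ** (mu + sd * z))

    for j, well in enumerate(wells):
        ctype = truth.type_of_well[well]
        if ctype == "none":
            continue
        components = truth.doublet_components.get(well, (ctype,))
        for i, spec in enumerate(cfg.analytes):
            vals = []
            for comp in components:
                v = draw(spec.pools[comp], well) if comp in spec.pools else 0.0
                if spec.background is not None:
                    v += draw(spec.background, well)
                vals.append(v)
            conc[i, j] = float(np.mean(vals))

    batches = [f"day{(int(w[1:].split('-')[0]) - 1) // 2 + 1}" for w in wells]
    met = MetaboliteMatrix(
        analytes=names,
        cells=wells,
        conc_uM=conc,
        below_loq=np.zeros_like(conc, dtype=bool),
        batch_of_cell=batches,
    )
    truth.conc_true = met
    return met


def _gene_mean_matrix(truth: SyntheticTruth, cfg: SimulationConfig,
                      genes: list[str], cell_types: list[str],
                      conc_by_analyte: dict[str, np.ndarray],
                      rng: np.random.Generator) -> np.ndarray:
    """Relative expression weights (genes x cells) before depth scaling."""
    n_g, n_c = len(genes), len(cell_types)
    special = cfg.special_genes()
    profile_rng = np.random.default_rng(np.random.SeedSequence((cfg.gene_profile_seed, 0)))
    base = profile_rng.lognormal(mean=0.0, sigma=cfg.gene_weight_log_sd, size=n_g)
    weights = np.repeat(base[:, None], n_c, axis=1)
    type_arr = np.array(cell_types)

    # driving analyte per trend gene: first in-situ analyte listing it
    driver: dict[str, AnalyteSpec] = {}
    leak: dict[str, float] = {}
    for spec in cfg.analytes:
        if spec.role == "in_situ":
            for g in spec.genes:
                driver.setdefault(g, spec)
        for g in spec.genes:
            leak[g] = max(leak.get(g, 0.0), spec.gene_leak)

    # broad per-type expression programs over generic genes (disjoint sets,
    # chosen from the fixed organism profile)
    generic_idx = [i for i, g in enumerate(genes)
                   if g not in special and g not in DE_GENES_B_UP and g != "NPF2.4"]
    order = profile_rng.permutation(len(generic_idx))
    programs: dict[str, list[int]] = {}
    pos = 0
    present_types = sorted(set(CELL_TYPES) & set(cfg.cell_type_props))
    for t in present_types:
        take = order[pos : pos + cfg.type_program_genes]
        programs[t] = [generic_idx[k] for k in take]
        pos += cfg.type_program_genes
    if truth is not None:
        truth.type_programs = {t: [genes[i] for i in idxs] for t, idxs in programs.items()}
    for t, idxs in programs.items():
        fold = np.where(type_arr == t, cfg.type_program_fold, 1.0)
        for i in idxs:
            weights[i] = base[i] * fold

    for i, g in enumerate(genes):
        if g in special:
            expressed = np.isin(type_arr, special[g])
            w = cfg.special_gene_weight
            if g in driver:
                spec = driver[g]
                conc = conc_by_analyte[spec.name]
                mu_ref = 10.0 ** spec.pools[spec.expressed_in[0] if spec.expressed_in[0] in spec.pools else list(spec.pools)[0]][0] \
                    if spec.pools else cfg.trend_c0_uM
                g_ref = float(trend_link(mu_ref, cfg))
                link = np.asarray(trend_link(conc, cfg)) / max(g_ref, 1e-12)
                weights[i] = np.where(expressed, w * link, 0.0)
            else:
                weights[i] = np.where(expressed, w, w * leak.get(g, 0.0))
        elif g in DE_GENES_B_UP:
            # expressed everywhere at a fixed baseline, 4x in the B subtype
            weights[i] = np.where(type_arr == "epidermis_B", 4.0, 1.0)
        elif g == "NPF2.4":
            # iridoid importer: epidermis-enriched, mirrors secologanin storage
            weights[i] = base[i] * np.where(np.isin(type_arr, EPIDERMIS), 5.0, 0.2)
    return weights


def simulate_counts(truth: SyntheticTruth, cfg: SimulationConfig) -> ExpressionSet:
    """Negative-binomial gene counts for every well (empty wells all-zero).

    Requires ``simulate_metabolites`` to have run first when any in-situ
    analyte has biosynthesis genes (their means follow the trend link of the
    true concentration); doublet wells are the element-wise sum of two
    independent component draws, exposed in
    ``truth.doublet_component_counts``.
    """
    if not truth.type_of_well:
        raise ConfigError("truth has no wells")
    if truth.conc_true is None:
        raise ConfigError("simulate_metabolites must run before simulate_counts")
    rng = _rng(cfg, 2)
    genes = cfg.gene_list()
    wells = list(truth.type_of_well)
    conc_df = truth.conc_true.to_frame()
    conc_by_analyte = {a: conc_df.loc[a, wells].to_numpy() for a in conc_df.index}

    # expand doublets into component pseudo-cells
    comp_wells: list[str] = []
    comp_types: list[str] = []
    comp_owner: list[int] = []
    for j, w in enumerate(wells):
        ctype = truth.type_of_well[w]
        if ctype == "none":
            continue
        for t in truth.doublet_components.get(w, (ctype,)):
            comp_wells.append(w)
            comp_types.append(t)
            comp_owner.append(j)

    conc_comp = {a: v[np.array(comp_owner, dtype=int)] if comp_owner else v[:0]
                 for a, v in conc_by_analyte.items()}
    weights = _gene_mean_matrix(truth, cfg, genes, comp_types, conc_comp, rng)
    col_sums = weights.sum(axis=0)
    col_sums[col_sums == 0] = 1.0
    depth = rng.lognormal(mean=np.log(cfg.depth_mean), sigma=cfg.depth_log_sd,
                          size=len(comp_wells))
    means = weights / col_sums * depth

    r = cfg.nb_dispersion
    with np.errstate(divide="ignore", invalid="ignore"):
        p = r / (r + means)
    draws = np.where(means > 0, rng.negative_binomial(r, np.clip(p, 1e-12, 1.0)), 0)

    counts = np.zeros((len(genes), len(wells)), dtype=np.int64)
    for k, j in enumerate(comp_owner):
        counts[:, j] += draws[:, k]
    for w, (t1, t2) in truth.doublet_components.items():
        ks = [k for k, ww in enumerate(comp_wells) if ww == w]
        truth.doublet_component_counts[w] = (draws[:, ks[0]].copy(), draws[:, ks[1]].copy())

    lengths = np.random.default_rng(
        np.random.SeedSequence((cfg.gene_profile_seed, 1))
    ).integers(500, 5000, size=len(genes))
    es = ExpressionSet(genes=genes, cells=wells, counts=counts, gene_length_bp=lengths)
    log.info("simulated counts %d genes x %d wells, seed %d", es.n_genes, es.n_cells, cfg.seed)
    return es


def simulate_peak_areas(
    met_true: MetaboliteMatrix,
    wells: list[WellRecord],
    cfg: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Forward model from true concentrations to calibration standards and
    per-well peak areas.

    The cell lysate is split in half; the analysis solution holds
    ``conc * V_cell / 2`` of analyte diluted into ``aliquot`` µL, and the
    instrument responds linearly (area = slope * conc_analysis + intercept)
    with multiplicative noise of the configured CV. Areas from analysis
    concentrations below the instrument floor are zero. Empty wells give zero
    area except for configured trace-background analytes.

    Returns (standards long table, analyte x well peak-area table).
    """
    rng = _rng(cfg, 4)
    names = met_true.analytes
    slopes = 10.0 ** rng.normal(cfg.calib_slope_log10_mean, cfg.calib_slope_log10_sd, len(names))
    ladder = np.geomspace(*cfg.calib_ladder_uM, cfg.calib_points)
    aliquot_uL = cfg.aliquot_volume_uL

    def noisy(a: np.ndarray) -> np.ndarray:
        if cfg.calib_cv == 0:
            return a
        return np.clip(a * (1.0 + cfg.calib_cv * rng.standard_normal(a.shape)), 0.0, None)

    std_rows = []
    for i, name in enumerate(names):
        for c in ladder:
            areas = noisy(np.full(cfg.calib_replicates, slopes[i] * c + cfg.calib_intercept))
            for rep, area in enumerate(areas, 1):
                std_rows.append((name, c, rep, float(area)))
    standards = pd.DataFrame(std_rows, columns=["analyte", "nominal_conc_uM", "replicate", "area"])

    by_id = {w.well_id: w for w in wells}
    area_mat = np.zeros((len(names), len(met_true.cells)))
    specs = {a.name: a for a in cfg.analytes}
    for j, well_id in enumerate(met_true.cells):
        w = by_id[well_id]
        if w.status is WellStatus.EMPTY:
            for i, name in enumerate(names):
                rate = specs[name].trace_empty_rate if name in specs else 0.0
                if rate > 0 and rng.random() < rate:
                    area_mat[i, j] = float(noisy(np.array(
                        [slopes[i] * cfg.trace_analysis_conc_uM + cfg.calib_intercept]))[0])
            continue
        v_cell_fL = math.pi / 6.0 * w.diameter_um**3
        # whole-cell amount: conc (µM = fmol/nL) x volume (fL = 1e-6 nL)
        half_amount_fmol = met_true.conc_uM[:, j] * v_cell_fL * 1e-6 / 2.0
        # analysis-solution conc (µM = pmol/µL): fmol -> pmol, per aliquot µL
        analysis_conc = half_amount_fmol / (aliquot_uL * 1e3)
        areas = noisy(slopes * analysis_conc + cfg.calib_intercept)
        areas[analysis_conc < cfg.instrument_floor_uM] = 0.0
        area_mat[:, j] = areas

    peak_areas = pd.DataFrame(area_mat, index=names, columns=met_true.cells)
    peak_areas.index.name = "analyte"
    log.info("simulated peak areas for %d analytes x %d wells", *peak_areas.shape)
    return standards, peak_areas


def simulate_experiment(cfg: SimulationConfig):
    """Convenience: run all four generator stages in order.

    Returns (wells, truth, expression, met_true, standards, peak_areas).
    """
    wells, truth = simulate_wells(cfg)
    met_true = simulate_metabolites(truth, cfg)
    expr = simulate_counts(truth, cfg)
    standards, areas = simulate_peak_areas(met_true, wells, cfg)
    return wells, truth, expr, met_true, standards, areas
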