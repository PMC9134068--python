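"""Pipeline drivers: zone summaries, model-data agreement, scenario
selection, long-distance transport assays, apoplast summaries, and the
synthetic DII-VENUS observation generator.

The observation generator is the stand-in for confocal nuclear-intensity
measurements: it forward-simulates a steady state, maps it through the
DII-VENUS network, and multiplies by log-normal noise (imaging intensities
are positive and heteroscedastic).  All randomness is seeded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dii import DIIParams, dii_steady_state, predict_dii
from .geometry import RootTemplate
from .model import (
    ModelError,
    ODESystem,
    PhysicalParams,
    ScenarioConfig,
    assemble_system,
    deposit_and_track,
    scenario,
    steady_state,
)
from .transporters import (
    Genotype,
    TransporterDistribution,
    WILD_TYPE,
    apply_genotype,
    build_distribution,
)

TISSUES = ("epidermis", "cortex")
ZONES = ("MZ", "EZ")


class ExperimentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Zone summaries and agreement
# ---------------------------------------------------------------------------


@dataclass
class ZoneSummary:
    """Mean +/- SE per (tissue, zone) bin; empty bins are flagged missing."""

    table: pd.DataFrame  # columns: tissue, zone, mean, se, n

    def value(self, tissue: str, zone: str, column: str = "mean") -> float:
        row = self.table[(self.table.tissue == tissue) & (self.table.zone == zone)]
        if row.empty:
            raise KeyError((tissue, zone))
        return float(row.iloc[0][column])

    @property
    def bins(self) -> list[tuple[str, str]]:
        return [tuple(r) for r in self.table[["tissue", "zone"]].itertuples(index=False)]

    def means(self) -> np.ndarray:
        return self.table["mean"].to_numpy()


def zone_summary(
    values: Mapping[int, float],
    template: RootTemplate,
    tissues: Sequence[str] = TISSUES,
    zones: Sequence[str] = ZONES,
) -> ZoneSummary:
    """Mean, standard error and n of a per-cell field per tissue x zone bin.

    SE is the sample standard deviation over sqrt(n).  A bin with no cells is
    reported with n = 0 and NaN statistics rather than silently zero.
    """
    rows = []
    for tissue in tissues:
        for zone in zones:
            vals = [
                values[c.id]
                for c in template.cells.values()
                if c.cell_type == tissue and c.zone == zone and c.id in values
            ]
            n = len(vals)
            if n == 0:
                rows.append((tissue, zone, math.nan, math.nan, 0))
            else:
                arr = np.asarray(vals, float)
                se = float(arr.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
                rows.append((tissue, zone, float(arr.mean()), se, n))
    return ZoneSummary(pd.DataFrame(rows, columns=["tissue", "zone", "mean", "se", "n"]))


@dataclass
class AgreementScore:
    score: float
    residuals: pd.DataFrame  # per-bin normalized residuals


def agreement(pred: ZoneSummary, obs: ZoneSummary) -> AgreementScore:
    """Scale-invariant discrepancy between two zone summaries.

    Both mean vectors are normalized to unit mean over the shared bins and
    the score is the sum of squared differences, so a pure rescaling of
    either summary scores 0 against itself.
    """
    if pred.bins != obs.bins:
        raise ExperimentError(f"bin mismatch: {pred.bins} vs {obs.bins}")
    p = pred.means()
    o = obs.means()
    if np.isnan(p).any() or np.isnan(o).any():
        raise ExperimentError("summaries contain missing bins")
    p_n = p / p.mean()
    o_n = o / o.mean()
    resid = p_n - o_n
    table = pred.table[["tissue", "zone"]].copy()
    table["residual"] = resid
    return AgreementScore(score=float(np.sum(resid**2)), residuals=table)


# ---------------------------------------------------------------------------
# Forward simulation helpers
# ---------------------------------------------------------------------------


def simulate_genotype(
    template: RootTemplate,
    scn: ScenarioConfig,
    geno: Genotype = WILD_TYPE,
    params: PhysicalParams | None = None,
    dist: TransporterDistribution | None = None,
    abcb4_mode: str = "efflux",
) -> tuple[ODESystem, np.ndarray]:
    """Assemble and solve the steady state for one genotype x scenario."""
    from .transporters import set_abcb4_mode

    params = params or PhysicalParams()
    base = dist if dist is not None else build_distribution(template)
    if abcb4_mode != base.abcb4_mode:
        base = set_abcb4_mode(base, abcb4_mode)
    d = apply_genotype(base, geno)
    system = assemble_system(template, d, scn, params)
    return system, steady_state(system)


def dii_zone_summary(
    template: RootTemplate,
    scn: ScenarioConfig,
    geno: Genotype = WILD_TYPE,
    params: PhysicalParams | None = None,
    dii_params: DIIParams = DIIParams(),
    dist: TransporterDistribution | None = None,
) -> ZoneSummary:
    system, x = simulate_genotype(template, scn, geno, params, dist)
    dii = predict_dii(system.state(x), dii_params)
    return zone_summary(dii.level, template)


# ---------------------------------------------------------------------------
# Synthetic observations
# ---------------------------------------------------------------------------


@dataclass
class SyntheticObservation:
    """Noisy per-cell DII-VENUS 'intensities' plus their zone summary."""

    intensity: dict[int, float]
    truth: dict[int, float]
    noise_sd: float
    seed: int
    summary: ZoneSummary


def generate_synthetic_observations(
    template: RootTemplate,
    scn: ScenarioConfig,
    geno: Genotype = WILD_TYPE,
    noise_sd: float = 0.1,
    seed: int = 0,
    params: PhysicalParams | None = None,
    dii_params: DIIParams = DIIParams(),
    dist: TransporterDistribution | None = None,
) -> SyntheticObservation:
    """Forward model + multiplicative log-normal noise exp(N(0, noise_sd^2)).

    Deterministic given ``seed``; ``noise_sd = 0`` reproduces the forward
    model exactly.
    """
    if noise_sd < 0:
        raise ExperimentError("noise_sd must be >= 0")
    system, x = simulate_genotype(template, scn, geno, params, dist)
    truth = predict_dii(system.state(x), dii_params).level
    rng = np.random.default_rng(seed)
    ids = sorted(truth)
    noise = np.exp(rng.normal(0.0, noise_sd, size=len(ids))) if noise_sd else np.ones(len(ids))
    obs = {cid: truth[cid] * noise[i] for i, cid in enumerate(ids)}
    return SyntheticObservation(
        intensity=obs,
        truth=truth,
        noise_sd=noise_sd,
        seed=seed,
        summary=zone_summary(obs, template),
    )


# ---------------------------------------------------------------------------
# Scenario selection
# ---------------------------------------------------------------------------


def scenario_selection(
    observations: Mapping[str, ZoneSummary],
    template: RootTemplate,
    scenarios: Sequence[str] = ("I", "II", "III", "IV", "V"),
    permeability_grid: Sequence[float] = (0.28, 0.56, 1.12),
    genotypes: Mapping[str, Genotype] | None = None,
    params: PhysicalParams | None = None,
    dii_params: DIIParams = DIIParams(),
    dist: TransporterDistribution | None = None,
) -> pd.DataFrame:
    """Score every scenario x permeability grid point against observed zone
    summaries across genotypes; return the ranking (best first).

    ``observations`` maps genotype names to observed summaries;
    ``genotypes`` maps the same names to Genotype objects (defaults to
    parsing the names).  Grid points whose simulation fails are recorded
    with an infinite score and skipped in the ranking.
    """
    from .transporters import genotype as parse_genotype

    if not permeability_grid:
        raise ExperimentError("permeability grid is empty")
    genotypes = genotypes or {name: parse_genotype(name) for name in observations}
    rows = []
    for sid in scenarios:
        for p in permeability_grid:
            total, failed = 0.0, False
            for name, obs in observations.items():
                try:
                    pred = dii_zone_summary(
                        template,
                        scenario(sid, p),
                        genotypes[name],
                        params,
                        dii_params,
                        dist,
                    )
                    total += agreement(pred, obs).score
                except (ModelError, ExperimentError) as e:
                    failed = True
                    break
            rows.append(
                (sid, p, math.inf if failed else total, failed)
            )
    df = pd.DataFrame(rows, columns=["scenario", "permeability", "score", "failed"])
    best = (
        df[~df.failed]
        .groupby("scenario", as_index=False)["score"]
        .min()
        .sort_values("score")
        .reset_index(drop=True)
    )
    best["rank"] = np.arange(1, len(best) + 1)
    return df.merge(best[["scenario", "rank"]], on="scenario", how="left").sort_values(
        ["rank", "score"]
    ).reset_index(drop=True)


def best_scenario(ranking: pd.DataFrame) -> str:
    ok = ranking[~ranking.failed]
    return str(ok.loc[ok.score.idxmin(), "scenario"])


# ---------------------------------------------------------------------------
# Long-distance transport assays
# ---------------------------------------------------------------------------


def _fraction_by_axis(template: RootTemplate, fraction: float, end: str) -> list[int]:
    """Cell ids of the apex-most / shoot-most ``fraction`` of cells."""
    ds = {c.id: template.axial_distance(c) for c in template.cells.values()}
    ordered = sorted(ds, key=ds.get, reverse=(end == "shoot"))
    k = max(1, int(round(fraction * len(ordered))))
    return ordered[:k]


def _shoot_cut_walls(template: RootTemplate) -> list[int]:
    out = set()
    for cid in template.shoot_boundary_cells:
        for s in template.segments_of_cell(cid):
            w = template.walls[s.wall_id]
            if s.face == "shootward" and w.is_boundary:
                out.add(w.id)
    return sorted(out)


def long_distance_assay(
    template: RootTemplate,
    genotypes: Mapping[str, Genotype],
    scenarios: Sequence[str],
    direction: str,
    permeability: float = 0.56,
    params: PhysicalParams | None = None,
    dist: TransporterDistribution | None = None,
    t_end: float = 3600.0,
    deposit_fraction: float = 0.1,
    readout_fraction: float | None = None,
    amount_multiple: float = 10.0,
    n_frames: int = 61,
) -> pd.DataFrame:
    """Radiolabel-style long-distance transport assay.

    ``direction="rootward"`` deposits a fixed amount of auxin over the
    shoot-boundary cells and reads the apical region after ``t_end``;
    ``"shootward"`` deposits at the root apex and reads the region near the
    shootward cut.  The deposited amount is the same for all genotypes
    (``amount_multiple`` times the wild-type steady-state mass of the
    deposit region).

    The readout is the retained-label share: deposit-derived auxin still in
    the readout region plus the label of auxin degraded there (a radiolabel
    stays in the segment as labelled metabolite), divided by the total label
    retained in the root.  Label that left through the shootward cut counts
    as part of the basal segment (the real root continues beyond the cut),
    while label rinsed off the cap surface is lost.  Values are normalized
    to wild-type per scenario; "WT" must be among the genotypes.
    """
    if direction not in ("rootward", "shootward"):
        raise ExperimentError(f"direction must be rootward or shootward, got {direction!r}")
    params = params or PhysicalParams()
    dist = dist if dist is not None else build_distribution(template)

    dep_end, read_end = ("shoot", "apex") if direction == "rootward" else ("apex", "shoot")
    if readout_fraction is None:
        # apical readout mirrors the deposit size; the basal segment is a
        # little larger since the cut captures through-transport
        readout_fraction = 0.1 if read_end == "apex" else 0.15
    dep_cells = _fraction_by_axis(template, deposit_fraction, dep_end)
    read_cells = _fraction_by_axis(template, readout_fraction, read_end)
    cut_walls = _shoot_cut_walls(template)
    areas = {cid: template.cells[cid].area for cid in template.cells}
    ts = np.linspace(0.0, t_end, n_frames)

    rows = []
    for sid in scenarios:
        scn = scenario(sid, permeability)
        wt_system = assemble_system(template, apply_genotype(dist, WILD_TYPE), scn, params)
        wt_base = steady_state(wt_system)
        region_mass = sum(
            wt_base[wt_system.cell_index[c]] * areas[c] for c in dep_cells
        )
        amount = amount_multiple * max(region_mass, 1e-12)
        for name, geno in genotypes.items():
            system = assemble_system(template, apply_genotype(dist, geno), scn, params)
            res = deposit_and_track(
                system, dep_cells, amount, t_end, output_times=ts, readout_region=read_cells
            )
            deltas = res["deposit"]
            integ = np.trapezoid(deltas, ts, axis=0)
            retained = deltas[-1] + params.degradation * integ
            cell_label = {
                c: retained[system.cell_index[c]] * areas[c] for c in template.cells
            }
            cut_label = sum(
                params.shoot_outflow
                * template.walls[wid].length
                * integ[system.wall_index[wid]]
                for wid in cut_walls
            )
            num = sum(cell_label[c] for c in read_cells)
            den = sum(cell_label.values())
            if read_end == "shoot":
                # label past the shootward cut is still in the basal segment
                num += cut_label
                den += cut_label
            rows.append((sid, name, num / den if den > 0 else math.nan))
    df = pd.DataFrame(rows, columns=["scenario", "genotype", "readout"])
    wt = df[df.genotype == "WT"].set_index("scenario")["readout"]
    df["normalized"] = [
        r.readout / wt[r.scenario] if wt.get(r.scenario, 0) else math.nan
        for r in df.itertuples()
    ]
    df["direction"] = direction
    return df


def redistribution_time(
    template: RootTemplate,
    scn: ScenarioConfig,
    direction: str,
    geno: Genotype = WILD_TYPE,
    params: PhysicalParams | None = None,
    dist: TransporterDistribution | None = None,
    corr_target: float = 0.95,
    t_max: float = 3600.0,
    dt: float = 30.0,
    deposit_fraction: float = 0.1,
    amount_multiple: float = 10.0,
) -> float:
    """Earliest time (s) at which the cellular auxin vector's Pearson
    correlation with the steady state reaches ``corr_target`` after a
    deposition at the shoot boundary (``direction="rootward"``) or the root
    apex (``"shootward"``)."""
    params = params or PhysicalParams()
    dist = dist if dist is not None else build_distribution(template)
    d = apply_genotype(dist, geno)
    system = assemble_system(template, d, scn, params)
    base = steady_state(system)

    dep_end = "shoot" if direction == "rootward" else "apex"
    dep_cells = _fraction_by_axis(template, deposit_fraction, dep_end)
    region_mass = sum(
        base[system.cell_index[c]] * template.cells[c].area for c in dep_cells
    )
    times = np.arange(0.0, t_max + dt / 2, dt)
    res = deposit_and_track(
        system, dep_cells, amount_multiple * region_mass, t_max, times, x0=base
    )
    nc = system.n_cells
    target = base[:nc]
    for t, x in zip(res["times"], res["states"]):
        r = np.corrcoef(x[:nc], target)[0, 1]
        if r >= corr_target:
            return float(t)
    raise ExperimentError(
        f"correlation target {corr_target} not reached within {t_max} s"
    )


# ---------------------------------------------------------------------------
# Apoplast summaries
# ---------------------------------------------------------------------------


def apoplast_summary(
    x: np.ndarray, system: ODESystem, mz_length: float = 210.0
) -> pd.DataFrame:
    """Mean apoplastic (wall-compartment) auxin per zone x interface type.

    A wall's zone comes from its midpoint's shootward distance from the QC
    (cap walls, below the QC, are labelled "cap"); the interface type is the
    sorted pair of adjacent tissue names, or "<tissue>|boundary".
    """
    tpl = system.template
    rows = []
    for wid, idx in system.wall_index.items():
        w = tpl.walls[wid]
        dist_ax = float(np.dot(w.midpoint - tpl.qc_position, tpl.axis))
        zone = "cap" if dist_ax < 0 else ("MZ" if dist_ax <= mz_length else "EZ")
        names = sorted(
            tpl.cells[cid].cell_type.split("_tier_")[0] for cid in w.cell_ids
        )
        iface = "|".join(names if len(names) == 2 else [names[0], "boundary"])
        rows.append((zone, iface, float(x[idx])))
    df = pd.DataFrame(rows, columns=["zone", "interface", "concentration"])
    return (
        df.groupby(["zone", "interface"], as_index=False)
        .agg(mean=("concentration", "mean"), n=("concentration", "size"))
        .sort_values(["zone", "interface"])
        .reset_index(drop=True)
    )
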