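"""Pipeline runner: configuration, provenance manifest and figures.

``run_pipeline`` drives a full analysis from a single serializable
:class:`RunConfig`: template generation, transporter assignment, genotype
application, steady states and DII-VENUS maps per scenario, zone summaries
and a scenario comparison table, all written to a run directory together
with a manifest recording the configuration hash, the seed and a checksum
of every output file.  Deterministic stages reproduce byte-identical
outputs for the same configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dii import predict_dii
from .experiments import dii_zone_summary, simulate_genotype, zone_summary
from .geometry import TemplateSpec, FileSpec, generate_regular_template, read_template, write_template
from .model import PhysicalParams, ModelError, scenario
from .transporters import WILD_TYPE, build_distribution, genotype

logger = logging.getLogger("rootflux")

KNOWN_SCENARIOS = ("I", "II", "III", "IV", "V")


@dataclass
class RunConfig:
    """Fully serializable description of a pipeline run."""

    scenarios: tuple[str, ...] = ("I", "II", "III", "IV", "V")
    genotype: str = "WT"
    permeability: float = 0.56
    template_path: str | None = None  # JSON template; None => generate
    template_spec: dict = field(default_factory=dict)  # TemplateSpec overrides
    params: dict = field(default_factory=dict)  # PhysicalParams overrides
    seed: int = 0
    figures: bool = False

    def validate(self) -> None:
        bad = [s for s in self.scenarios if s not in KNOWN_SCENARIOS]
        if bad:
            raise ModelError(f"unknown scenario(s) {bad}; choose from {KNOWN_SCENARIOS}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run all configured stages and write outputs plus a manifest.

    Raises on any stage failure after flagging partial outputs in the
    manifest.  Returns the run directory.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.digest,
        "seed": config.seed,
        "outputs": {},
        "status": "running",
    }

    def record(path: Path):
        manifest["outputs"][path.name] = _checksum(path)

    try:
        if config.template_path:
            tpl = read_template(config.template_path)
        else:
            spec_kwargs = dict(config.template_spec)
            if "files" in spec_kwargs:
                spec_kwargs["files"] = [FileSpec(**f) for f in spec_kwargs["files"]]
            tpl = generate_regular_template(TemplateSpec(**spec_kwargs))
        tpl_path = out / "template.json"
        write_template(tpl, tpl_path)
        record(tpl_path)
        logger.info("template: %d cells, %d walls", len(tpl.cells), len(tpl.walls))

        params = PhysicalParams(**config.params)
        dist = build_distribution(tpl)
        geno = genotype(config.genotype)

        comparison = []
        for sid in config.scenarios:
            scn = scenario(sid, config.permeability)
            system, x = simulate_genotype(tpl, scn, geno, params, dist)
            logger.info("scenario %s: steady state solved (n=%d)", sid, system.n)
            logger.debug(
                "scenario %s residual: %.3e",
                sid,
                np.abs(system.matrix @ x + system.source).max(),
            )

            state_path = out / f"steady_state_{sid}.csv"
            rows = [
                (cid, tpl.cells[cid].cell_type, tpl.cells[cid].zone or "", float(x[i]))
                for cid, i in system.cell_index.items()
            ]
            pd.DataFrame(
                rows, columns=["cell_id", "cell_type", "zone", "concentration"]
            ).to_csv(state_path, index=False)
            record(state_path)

            dii_levels = predict_dii(system.state(x)).level
            dii_path = out / f"dii_{sid}.csv"
            pd.DataFrame(
                sorted(dii_levels.items()), columns=["cell_id", "dii_level"]
            ).to_csv(dii_path, index=False)
            record(dii_path)

            zs = zone_summary(dii_levels, tpl)
            zs_path = out / f"zones_{sid}.csv"
            zs.table.to_csv(zs_path, index=False)
            record(zs_path)

            for r in zs.table.itertuples():
                comparison.append((sid, r.tissue, r.zone, r.mean, r.se, r.n))

            if config.figures:
                _write_figure(tpl, x, system, out / f"auxin_{sid}.png")
                record(out / f"auxin_{sid}.png")

        cmp_path = out / "scenario_comparison.csv"
        pd.DataFrame(
            comparison, columns=["scenario", "tissue", "zone", "dii_mean", "dii_se", "n"]
        ).to_csv(cmp_path, index=False)
        record(cmp_path)
        manifest["status"] = "ok"
    except Exception:
        manifest["status"] = "failed"
        raise
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def _write_figure(tpl, x, system, path: Path):
    """Headless polygon heatmap of the cellular auxin field."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.collections import PolyCollection

    polys = []
    vals = []
    for cid, i in system.cell_index.items():
        polys.append(tpl.cells[cid].vertices)
        vals.append(x[i])
    fig, ax = plt.subplots(figsize=(4, 8))
    coll = PolyCollection(polys, array=np.asarray(vals), edgecolor="k", linewidth=0.2)
    ax.add_collection(coll)
    ax.autoscale()
    ax.set_aspect("equal")
    ax.set_xlabel("x (um)")
    ax.set_ylabel("shootward distance from QC (um)")
    fig.colorbar(coll, ax=ax, label="auxin (uM)")
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
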