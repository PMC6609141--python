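"""End-to-end orchestration: simulate -> cost -> analyse -> decision outputs.

Every run writes a manifest (config snapshot, seeds, package version, input
digests, timestamps) so any table or figure can be regenerated.  All
numeric outputs are deterministic for a fixed seed; timestamps live only in
the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, cea, programme
from .costing import WAVES, UnitCostTable
from .dataset import TrialData, build_analysis_dataset, complete_cases
from .inference import IncrementalEstimates, cluster_bootstrap
from .sensitivity import SensitivityConfig, run_variant
from .synthetic import GeneratorConfig, SimulatedTrial, describe, generate

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "render_tables",
    "waves_to_long",
    "long_to_waves",
    "plot_ce_plane",
    "plot_ceac",
]


@dataclass
class PipelineConfig:
    """Single structured configuration for a full run.

    ``generator`` holds the synthetic-trial settings; the remaining fields
    control the analysis.  CLI flags override these values.
    """

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    bootstrap_B: int = 1000
    scenario: str = "full"
    wtp_upper: float = 2000.0
    wtp_step: float = 5.0
    variants: tuple = ()  # sensitivity variants to run, e.g. ("costs_up_5",)
    adjusted: bool = True
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.pop("generator", {}))
        return cls(generator=gen, **raw)


# ---------------------------------------------------------------------------
# long <-> wide service-use serialisation
# ---------------------------------------------------------------------------

def waves_to_long(waves: pd.DataFrame) -> pd.DataFrame:
    """Wide wave rows -> long (pupil_id, wave, service_id, count).  An empty
    count marks a blank item; a (pupil, wave) with no rows is wave-missing."""
    return waves.melt(
        id_vars=["pupil_id", "wave"], var_name="service_id", value_name="count"
    ).sort_values(["pupil_id", "wave", "service_id"], kind="stable", ignore_index=True)


def long_to_waves(long: pd.DataFrame) -> pd.DataFrame:
    """Inverse of :func:`waves_to_long`."""
    wide = long.pivot(index=["pupil_id", "wave"], columns="service_id", values="count")
    wide.columns.name = None
    return wide.reset_index()


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_pipeline(
    config: PipelineConfig,
    out_dir,
    trial: SimulatedTrial | None = None,
    write_figures: bool = False,
) -> dict:
    """Execute the full analysis and write the results bundle to ``out_dir``.

    Stages: synthetic-trial generation (unless ``trial`` is supplied) ->
    costing -> programme costing -> bootstrap inference -> CE plane / CEAC
    -> requested sensitivity variants.  Returns the bundle as a dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = datetime.now(timezone.utc).isoformat()

    if trial is None:
        gen_config = config.generator.with_(seed=config.seed)
        logger.info("simulate: %d schools", gen_config.n_schools)
        trial = generate(gen_config)
    else:
        gen_config = config.generator

    table = UnitCostTable.default()
    trial_data = TrialData(waves=trial.waves, pupils=trial.pupils, table=table)
    analysis = build_analysis_dataset(trial_data)
    cc = complete_cases(analysis)
    logger.info(
        "costing: %d pupils in, %d complete cases retained (%d excluded)",
        len(analysis), len(cc), len(analysis) - len(cc),
    )

    prog = programme.aggregate(programme.ProgrammeCostLedger.default(), config.scenario)
    per_pupil = float(round(prog.per_pupil))
    cc = programme.add_programme_cost(cc, per_pupil)

    estimates = cluster_bootstrap(
        cc, B=config.bootstrap_B, seed=config.seed, adjusted=config.adjusted
    )
    dominance = cea.classify(estimates.delta_c, estimates.delta_e, estimates.ci_c, estimates.ci_e)
    grid = cea.default_lambda_grid(config.wtp_upper, config.wtp_step)
    curve = cea.ceac(estimates.replicates, grid)
    proportions, plane = cea.ce_plane_summary(estimates.replicates)

    sens_rows = []
    for variant in config.variants:
        row = run_variant(
            SensitivityConfig(variant=variant, seed=config.seed, B=config.bootstrap_B),
            trial_data,
        )
        sens_rows.append(
            {k: v for k, v in row.items() if k not in ("estimates", "pooled_cost", "pooled_effect")}
        )

    bundle = {
        "analysis": analysis,
        "descriptives": describe(analysis),
        "programme": prog,
        "programme_per_pupil": per_pupil,
        "estimates": estimates,
        "dominance": dominance,
        "ceac": curve,
        "plane_proportions": proportions,
        "plane": plane,
        "sensitivity": pd.DataFrame(sens_rows),
        "truth": trial.truth,
    }

    # --- write outputs ---------------------------------------------------
    costs_cols = [
        "pupil_id", "baseline_cost", "total_cost",
        "education_cost", "health_cost", "criminal_cost", "complete",
    ]
    analysis[costs_cols].rename(columns={"total_cost": "total_discounted"}).to_csv(
        out / "costs.csv", index=False
    )
    est_payload = {
        **estimates.to_dict(),
        "replicates": estimates.replicates,
        "dominance": asdict(dominance),
        "programme": prog.rounded(),
        "plane_proportions": proportions,
        "truth": trial.truth,
    }
    (out / "estimates.json").write_text(
        json.dumps(est_payload, default=_jsonable, sort_keys=True, indent=1)
    )
    curve.to_frame().to_csv(out / "ceac.csv", index=False)
    plane.to_csv(out / "plane.csv", index=False)
    if sens_rows:
        bundle["sensitivity"].to_csv(out / "sensitivity_results.csv", index=False)
    if write_figures:
        plot_ce_plane(plane, out / "ce_plane.png")
        plot_ceac(curve, out / "ceac.png")

    manifest = {
        "package": "trialcea",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "generator": asdict(gen_config),
            "bootstrap_B": config.bootstrap_B,
            "scenario": config.scenario,
            "wtp_upper": config.wtp_upper,
            "wtp_step": config.wtp_step,
            "variants": list(config.variants),
            "adjusted": config.adjusted,
        },
        "started": started,
        "finished": datetime.now(timezone.utc).isoformat(),
        "outputs": {
            p.name: _digest(p)
            for p in sorted(out.iterdir())
            if p.suffix in (".csv", ".json") and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, default=_jsonable, indent=1))
    bundle["manifest"] = manifest
    return bundle


# ---------------------------------------------------------------------------
# report rendering
# ---------------------------------------------------------------------------

def _fmt_ci(ci, nd=2) -> str:
    return f"({ci[0]:.{nd}f}, {ci[1]:.{nd}f})"


def render_programme_table(summary: programme.ProgrammeCostSummary,
                           ledger: programme.ProgrammeCostLedger | None = None) -> str:
    """Programme-cost table with whole-pound figures, mirroring the shipped
    ledger layout (components, stage subtotals, total, per school/pupil)."""
    ledger = ledger or programme.ProgrammeCostLedger.default()
    r = summary.rounded()
    lines = ["Programme cost (GBP)", ""]
    comp = ledger.components
    if summary.scenario == "no_parental":
        comp = comp.loc[~comp["parental"]]
    elif summary.scenario == "classroom_only":
        comp = comp.loc[comp["stage"] == 1]
    for stage, subtotal in ((1, r["stage1_subtotal"]), (2, r["stage2_subtotal"])):
        rows = comp.loc[comp["stage"] == stage]
        if rows.empty and stage == 2:
            continue
        lines.append(f"Stage {stage}:")
        for _, row in rows.iterrows():
            lines.append(f"  {row['label']:<40s} {round(row['amount']):>8d}")
        lines.append(f"  {'Stage ' + str(stage) + ' subtotal':<40s} {subtotal:>8d}")
    lines.append(f"  {'Total cost':<40s} {r['total']:>8d}")
    lines.append(f"  {'Mean cost/school':<40s} {r['per_school']:>8d}")
    lines.append(f"  {'Mean cost/pupil':<40s} {r['per_pupil']:>8d}")
    return "\n".join(lines)


def render_tables(bundle: dict) -> str:
    """Formatted plain-text report of a results bundle: programme costs
    (whole GBP), incremental cost (2 d.p.) and effect (2 d.p. proportions)
    with bootstrap CIs, quadrant shares, and the sensitivity table when
    variants were run."""
    for key in ("programme", "estimates", "dominance", "plane_proportions"):
        if key not in bundle:
            raise KeyError(f"results bundle missing component: {key!r}")
    est: IncrementalEstimates = bundle["estimates"]
    dom = bundle["dominance"]
    parts = [render_programme_table(bundle["programme"]), ""]
    parts.append("Incremental results (bootstrap 95% CI)")
    parts.append(
        f"  Difference in total costs (GBP): {est.delta_c:.2f} {_fmt_ci(est.ci_c)}"
    )
    parts.append(
        f"  Difference in effect (HED cases avoided): {est.delta_e:.2f} {_fmt_ci(est.ci_e)}"
    )
    icer = dom.icer if isinstance(dom.icer, str) else f"{dom.icer:.2f}"
    parts.append(f"  Decision: {dom.label} ({dom.quadrant} quadrant); ICER: {icer}")
    props = bundle["plane_proportions"]
    parts.append(
        "  CE-plane quadrant shares: "
        + ", ".join(f"{q}={props[q]:.2f}" for q in ("NE", "SE", "NW", "SW"))
    )
    sens = bundle.get("sensitivity")
    if sens is not None and len(sens):
        parts.append("")
        parts.append("Sensitivity analyses")
        for _, row in sens.iterrows():
            parts.append(
                f"  {row['variant']:<24s} n={row['n_intervention']}/{row['n_control']}  "
                f"dC={row['delta_c']:.2f} {_fmt_ci(row['ci_c'])}  "
                f"dE={row['delta_e']:.2f} {_fmt_ci(row['ci_e'])}"
            )
    return "\n".join(parts)


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def plot_ce_plane(plane: pd.DataFrame, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(plane["delta_e"], plane["delta_c"], s=6, alpha=0.4)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental effect (HED cases avoided)")
    ax.set_ylabel("Incremental cost (GBP)")
    ax.set_title("Cost-effectiveness plane")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ceac(curve: cea.CEACCurve, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.lambda_grid, curve.probabilities)
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (GBP per HED case avoided)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
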