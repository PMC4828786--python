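"""End-to-end workflow: synthetic bench run -> forward model -> validation.

Mirrors the validation loop of the emulated study on synthetic data:
generate a noisy "experimental" inflation curve, run the clean forward
simulation, compare the two at equal volume, and write a report bundle
(CSV curves, JSON report, P-V / d-V plot).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

from .config import RunConfig
from .errors import InvalidInputError
from .metrics import compare_curves
from .synthetic import gen_inflation_experiment

logger = logging.getLogger("balloonmech")


def run_workflow(
    config: RunConfig,
    mode: str = "free",
    seed: int | None = None,
    outdir: str | Path | None = None,
    n_grid: int = 200,
) -> dict:
    """Run one synthetic validation workflow and return the report dict.

    ``mode`` selects free inflation or inflation inside the configured
    phantom; ``seed`` overrides the config noise seed.  When ``outdir``
    is given, the experimental/computational curves, a JSON report and a
    static P-V / d-V figure are written there.
    """
    if mode not in ("free", "constrained"):
        raise InvalidInputError("mode must be 'free' or 'constrained'")
    if mode == "constrained" and config.phantom is None:
        raise InvalidInputError("constrained mode requires a phantom section in the config")

    design = config.design.to_design()
    material = config.material.to_material()
    protocol = config.protocol.to_protocol()
    options = config.solver.to_options()
    noise = config.noise.to_noise(seed)
    phantom = config.phantom.to_phantom() if mode == "constrained" else None
    phantom_material = config.phantom.to_material() if mode == "constrained" else None

    cfg_hash = hashlib.sha256(
        json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    ).hexdigest()[:12]
    logger.info("workflow mode=%s seed=%s config=%s", mode, noise.seed, cfg_hash)

    logger.info("stage=synthetic-experiment")
    synth = gen_inflation_experiment(
        design, material, protocol,
        phantom=phantom, phantom_material=phantom_material,
        noise=noise, n_elements=config.solver.n_elements, options=options,
    )
    logger.info("stage=compare")
    cmp_result = compare_curves(synth.experiment, synth.truth, n_grid=n_grid)

    report = {
        "mode": mode,
        "seed": noise.seed,
        "config_hash": cfg_hash,
        **cmp_result.report(),
        "max_diameter_mm": float(max(s.max_diameter_mm() for s in synth.result.states)),
    }
    if synth.result.contact_report is not None:
        report["contact"] = {
            k: float(v) if isinstance(v, (int, float)) else v
            for k, v in synth.result.contact_report.items()
        }

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        synth.experiment.to_csv(outdir / "experimental.csv")
        synth.truth.to_csv(outdir / "computational.csv")
        (outdir / "report.json").write_text(json.dumps(report, indent=2))
        _plot_curves(synth, outdir / "pv_dv.png")
        logger.info("stage=write out=%s", outdir)
    return report


def _plot_curves(synth, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_p, ax_d) = plt.subplots(1, 2, figsize=(9, 3.6))
    for curve, style, label in (
        (synth.experiment, "o", "experimental (synthetic)"),
        (synth.truth, "-", "computational"),
    ):
        ax_p.plot(curve.volume_ml, curve.pressure_mmhg, style, label=label, ms=3)
        ax_d.plot(curve.volume_ml, curve.diameter_mm, style, label=label, ms=3)
    ax_p.set_xlabel("V (ml)")
    ax_p.set_ylabel("P (mmHg)")
    ax_d.set_xlabel("V (ml)")
    ax_d.set_ylabel("d (mm)")
    ax_p.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
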