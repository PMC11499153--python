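"""Agar calibration: recover the transport number n and free D.

Simulates the pre-experiment recording in dilute agar (free medium:
alpha = 1, lambda = 1, k' = 0) with 2% multiplicative electrode noise and
fits the two remaining unknowns of the source model.  These (n, D) values
are what the tissue fits in 03 hold fixed.  Writes results/agar_fit.json.
"""

import json
from pathlib import Path

from ecsastro.rti_fitting import fit_agar, preprocess_curve
from ecsastro.rti_model import DiffusionParams
from ecsastro.synthetic_data import (CurveSimConfig, DEFAULT_CALIBRATION,
                                     simulate_diffusion_trace)

OUT = Path(__file__).resolve().parents[1] / "results"
TRUTH = DiffusionParams.free_medium(D=1.2e-5, n_transport=0.35)


def main(seed: int = 21) -> None:
    OUT.mkdir(exist_ok=True)
    cfg = CurveSimConfig(params_true=TRUTH, noise_sigma_rel=0.02, seed=seed)
    trace = simulate_diffusion_trace(cfg, medium_label="agar")
    curve = preprocess_curve(trace.voltage_mV, trace.times,
                             DEFAULT_CALIBRATION, cfg.source,
                             t_on=0.0, medium_label="agar")
    res = fit_agar(curve)
    report = {"n_transport": res.params.n_transport, "D_cm2_per_s": res.params.D,
              "sse_mM2": res.sse, "converged": res.converged,
              "truth": {"n_transport": TRUTH.n_transport, "D_cm2_per_s": TRUTH.D}}
    (OUT / "agar_fit.json").write_text(json.dumps(report, indent=2))
    print(f"n = {res.params.n_transport:.4f} (truth {TRUTH.n_transport}), "
          f"D = {res.params.D:.3e} cm²/s (truth {TRUTH.D:.3e}), "
          f"converged = {res.converged}")


if __name__ == "__main__":
    main()
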