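import numpy as np
import pytest

from leafwave.calibration import CalibrationCurve
from leafwave.synth import make_fields, preset, render_stack

SA_KD = 32.0
SA_RMAX = 0.462


@pytest.fixture(scope="session")
def sa_curve() -> CalibrationCurve:
    """The SA sensor calibration: K_D = 32 µM, 46.2 % saturation quench."""
    return CalibrationCurve(analyte="sa", kd=SA_KD, r_max=SA_RMAX)


@pytest.fixture(scope="session")
def preset_truths():
    """Noise-free ground truth of every stress archetype (computed once)."""
    out = {}
    for label in ("wounding", "xcc", "light", "heat"):
        cfg = preset(label)
        out[label] = (cfg, make_fields(cfg), cfg.rois())
    return out


@pytest.fixture(scope="session")
def xcc_stack(preset_truths):
    """One rendered noisy Xcc stack shared across imaging-level tests."""
    cfg, truth, rois = preset_truths["xcc"]
    stack, rois = render_stack(truth, cfg)
    return cfg, truth, stack, rois


def gaussian_series(sigma: float, peak_time: float = 60.0, amp: float = 10.0,
                    dt: float = 1.0, t_stress: float = 10.0, t_end: float = 150.0):
    """A Gaussian concentration pulse on a regular grid."""
    from leafwave.wave_features import ConcentrationSeries

    t = np.arange(0.0, t_end + dt / 2, dt)
    v = amp * np.exp(-((t - peak_time) ** 2) / (2 * sigma**2))
    return ConcentrationSeries(times=t, values=v, t_stress=t_stress)
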