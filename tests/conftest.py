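import numpy as np
import pytest

from placentile import synthetic_data as sd
from placentile.chart_models import FittedChartModel, ParamCurve, ParamCurves

GA_LO, GA_HI = 79.0, 99.0


def model_from_curves(family, mu, sigma, nu, tau=(2.0, 2.0)):
    """Build a chart model directly from known linear-in-eta parameter curves.

    ``mu``/``sigma``/``nu``/``tau`` are (start, end) value pairs over the
    79-99-day age range; scalars give constant curves.  Lets tests exercise
    centile/calibration machinery against an exactly known truth without
    going through fitting.
    """
    links = {"mu": "log", "sigma": "log", "nu": "log" if family == "SEP3" else "identity", "tau": "log"}
    center = (GA_LO + GA_HI) / 2.0
    scale = (GA_HI - GA_LO) / 2.0
    curves = {}
    for name, spec in (("mu", mu), ("sigma", sigma), ("nu", nu), ("tau", tau)):
        pair = (spec, spec) if np.isscalar(spec) else tuple(spec)
        link = links[name]
        eta = [np.log(v) if link == "log" else float(v) for v in pair]
        if eta[0] == eta[1]:
            curves[name] = ParamCurve(name, link, "constant", np.array([eta[0]]), edf=1.0)
        else:
            # eta(t) = a + b * (t - center)/scale  with eta(79)=eta0, eta(99)=eta1
            a = (eta[0] + eta[1]) / 2.0
            b = (eta[1] - eta[0]) / 2.0
            curves[name] = ParamCurve(
                name, link, "linear", np.array([a, b]), edf=2.0, t_center=center, t_scale=scale
            )
    pc = ParamCurves(family, curves, GA_LO, GA_HI)
    return FittedChartModel(pc, loglik=np.nan, total_edf=sum(c.edf for c in curves.values()), aic=np.nan)


@pytest.fixture(scope="session")
def small_cohort():
    """One shared synthetic cohort, modest size, fixed seed."""
    return sd.generate_cohort(n=600, seed=7)


@pytest.fixture(scope="session")
def truth_model():
    """A BCPEo chart model with gently age-varying known parameters."""
    return model_from_curves("BCPEo", mu=(0.16, 0.22), sigma=(0.40, 0.45), nu=0.45, tau=2.0)
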