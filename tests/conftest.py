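import numpy as np
import pytest

from bandspect import synthetic as syn
from bandspect.input_function import InputFunction
from bandspect.schedule import default_frame_schedule


@pytest.fixture(scope="session")
def schedule():
    return default_frame_schedule()


@pytest.fixture(scope="session")
def blood_truth(schedule):
    """Noiseless blood simulation with default parameters."""
    return syn.simulate_blood(syn.BloodModelParams(), schedule, noise_sd=0.0, seed=1)


@pytest.fixture(scope="session")
def true_input(blood_truth):
    """The generator's true parent plasma curve as an InputFunction."""
    return blood_truth.true_parent_plasma


@pytest.fixture(scope="session")
def small_phantom():
    return syn.default_phantom(shape=(20, 20, 20))


@pytest.fixture(scope="session")
def full_phantom():
    return syn.default_phantom()


def piecewise_linear_exp_conv(nodes_t, nodes_c, beta, t_eval):
    """Analytic convolution of a piecewise-linear curve with exp(-beta t).

    Independent oracle: closed-form per-segment integration of
    int_0^t C(s) exp(-beta (t - s)) ds for C linear on each segment.
    """
    nodes_t = np.asarray(nodes_t, float)
    nodes_c = np.asarray(nodes_c, float)
    t_eval = np.asarray(t_eval, float)
    out = np.zeros_like(t_eval)
    for a, b, ca, cb in zip(nodes_t[:-1], nodes_t[1:], nodes_c[:-1], nodes_c[1:]):
        m = (cb - ca) / (b - a)
        # full segments (t >= b)
        full = t_eval >= b
        tf = t_eval[full]
        upper = np.exp(-beta * (tf - b)) * (ca / beta + m * ((b - a) / beta - 1 / beta**2))
        lower = np.exp(-beta * (tf - a)) * (ca / beta - m / beta**2)
        out[full] += upper - lower
        # partial segments (a < t < b)
        part = (t_eval > a) & (t_eval < b)
        tp = t_eval[part]
        upper_p = (ca + m * (tp - a)) / beta - m / beta**2
        lower_p = np.exp(-beta * (tp - a)) * (ca / beta - m / beta**2)
        out[part] += upper_p - lower_p
    return out


@pytest.fixture(scope="session")
def boxcar_oracle(schedule):
    """Boxcar input on the 1 s grid + analytic frame-averaged convolution."""
    t = np.arange(0.0, schedule.end_s[-1] + 1.0)
    c, t0, t1 = 2.0, 100.0, 400.0
    cp = np.where((t >= t0) & (t < t1), c, 0.0)
    inp = InputFunction(t, cp)
    # the sampled boxcar is piecewise linear with 1 s ramps at the edges
    nodes_t = [0.0, t0 - 1.0, t0, t1 - 1.0, t1, t[-1]]
    nodes_c = [0.0, 0.0, c, c, 0.0, 0.0]

    def frame_averages(beta, dt=0.05):
        tf = np.arange(0.0, schedule.end_s[-1] + dt / 2, dt)
        conv = piecewise_linear_exp_conv(nodes_t, nodes_c, beta, tf)
        cum = np.concatenate([[0.0], np.cumsum((conv[1:] + conv[:-1]) * dt / 2)])
        s = np.rint(schedule.start_s / dt).astype(int)
        e = np.rint(schedule.end_s / dt).astype(int)
        return (cum[e] - cum[s]) / schedule.duration_s

    return inp, frame_averages
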