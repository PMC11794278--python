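import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def naive_layer_sim(weights, times, t_max, v_th, v_reset, theta):
    """Scalar per-step reference simulation of one IF layer.

    Pure-python loops over time and neurons; independent of the vectorized
    implementation.  Firing requires potential >= v_th + theta*t and
    potential strictly above rest, evaluated after integration at each step.
    """
    n_pre, n_post = len(weights), len(weights[0])
    potential = [float(v_reset)] * n_post
    fired = [False] * n_post
    fire_time = [t_max] * n_post
    for t in range(t_max + 1):
        for j in range(n_post):
            if fired[j]:
                continue
            for i in range(n_pre):
                if times[i] == t:
                    potential[j] += weights[i][j]
        threshold = v_th + theta * t
        for j in range(n_post):
            if not fired[j] and potential[j] >= threshold and potential[j] > v_reset:
                fired[j] = True
                fire_time[j] = t
                potential[j] = v_reset
    return fire_time
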