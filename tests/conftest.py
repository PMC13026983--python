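import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sonoflow import DecisionMatrix

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


# Six-scenario KPI averages from the motivating ultrasonography-department
# study: the worked decision-matrix example used throughout the tests.
SCENARIOS = ("S1", "S2", "S3", "S4", "S5", "S6")
KPI_AVERAGES = {
    "AWT": (40.87, 23.68, 36.43, 14.80, 46.28, 35.56),
    "WIP": (13.55, 9.45, 10.43, 6.63, 14.28, 11.49),
    "PST": (62.17, 50.98, 58.02, 42.87, 68.68, 63.01),
    "UtilADC": (0.43, 0.54, 0.39, 0.47, 0.44, 0.57),
}
KPI_DIRECTIONS = {"AWT": "min", "WIP": "min", "PST": "min", "UtilADC": "max"}


@pytest.fixture
def scenario_kpi_matrix() -> DecisionMatrix:
    criteria = tuple(KPI_AVERAGES)
    values = np.column_stack([KPI_AVERAGES[c] for c in criteria])
    return DecisionMatrix(
        values=values,
        alternatives=SCENARIOS,
        criteria=criteria,
        directions=tuple(KPI_DIRECTIONS[c] for c in criteria),
    )


def topsis_oracle(a: np.ndarray, weights: np.ndarray, directions):
    """Independent loop-based TOPSIS for cross-checking the implementation.

    Follows the textbook steps one scalar at a time, sharing no code with
    sonoflow.topsis.
    """
    m, n = a.shape
    nij = [[0.0] * n for _ in range(m)]
    for j in range(n):
        col_norm = sum(a[i][j] ** 2 for i in range(m)) ** 0.5
        for i in range(m):
            nij[i][j] = a[i][j] / col_norm
    vij = [[weights[j] * nij[i][j] for j in range(n)] for i in range(m)]
    a_plus, a_minus = [], []
    for j in range(n):
        col = [vij[i][j] for i in range(m)]
        if directions[j] == "max":
            a_plus.append(max(col))
            a_minus.append(min(col))
        else:
            a_plus.append(min(col))
            a_minus.append(max(col))
    s_plus = [sum((vij[i][j] - a_plus[j]) ** 2 for j in range(n)) ** 0.5 for i in range(m)]
    s_minus = [sum((vij[i][j] - a_minus[j]) ** 2 for j in range(n)) ** 0.5 for i in range(m)]
    ci = [s_minus[i] / (s_minus[i] + s_plus[i]) for i in range(m)]
    order = sorted(range(m), key=lambda i: (-ci[i], i))
    ranks = [0] * m
    for pos, i in enumerate(order, start=1):
        ranks[i] = pos
    return {
        "n": nij, "v": vij, "a_plus": a_plus, "a_minus": a_minus,
        "s_plus": s_plus, "s_minus": s_minus, "ci": ci, "ranks": ranks,
    }
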