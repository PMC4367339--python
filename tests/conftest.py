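import numpy as np
import pytest
from hypothesis import settings

from odorblend.io import builtin_thresholds, load_validation_fixture, thresholds_by_name
from odorblend.mixture_model import extended_model

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def thresholds():
    return thresholds_by_name(builtin_thresholds())


@pytest.fixture(scope="session")
def validation_rows():
    return load_validation_fixture()


@pytest.fixture
def pooled_curve():
    return extended_model()


# ---------------------------------------------------------------------------
# independent brute-force oracles (closed-form normal equations, no lstsq)
# ---------------------------------------------------------------------------

def _solve3_cramer(A, b):
    A = [[float(v) for v in row] for row in A]
    b = [float(v) for v in b]

    def det3(m):
        return (
            m[0][0] * (m[1][1] * m[2][2] - m[1][2] * m[2][1])
            - m[0][1] * (m[1][0] * m[2][2] - m[1][2] * m[2][0])
            + m[0][2] * (m[1][0] * m[2][1] - m[1][1] * m[2][0])
        )

    d = det3(A)
    out = []
    for k in range(3):
        Ak = [[A[i][j] if j != k else b[i] for j in range(3)] for i in range(3)]
        out.append(det3(Ak) / d)
    return out


def brute_force_line(points):
    """Closed-form simple-regression slope/intercept from raw sums."""
    xs = [float(p[0]) for p in points]
    ys = [float(p[1]) for p in points]
    n = len(xs)
    sx, sy = sum(xs), sum(ys)
    sxx = sum(x * x for x in xs)
    sxy = sum(x * y for x, y in zip(xs, ys))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    return slope, intercept


def brute_force_quadratic(xs, ys):
    """Normal equations for y = a2 x² + a1 x + a0 solved by Cramer's rule."""
    xs = [float(x) for x in xs]
    ys = [float(y) for y in ys]
    s = [sum(x**k for x in xs) for k in range(5)]
    t = [sum(y * x**k for x, y in zip(xs, ys)) for k in range(3)]
    A = [[s[4], s[3], s[2]], [s[3], s[2], s[1]], [s[2], s[1], s[0]]]
    b = [t[2], t[1], t[0]]
    return _solve3_cramer(A, b)
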