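import numpy as np
import pytest

from lpadapt.oracles import Oracle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_disk_oracle(radius: float = 1.0, center=(0.0, 0.0)) -> Oracle:
    """Euclidean disk membership oracle with known area."""
    c = np.asarray(center, float)
    r2 = radius * radius
    return Oracle(
        lambda x: float((x - c) @ (x - c)) <= r2,
        n=2,
        name="disk",
        batch_predicate=lambda pts: ((pts - c) ** 2).sum(axis=1) <= r2,
        true_volume=np.pi * r2,
        bounding_box=np.stack([c - radius, c + radius], axis=1),
    )


def make_ball_oracle(n: int, radius: float = 1.0) -> Oracle:
    """n-dimensional Euclidean ball oracle."""
    r2 = radius * radius
    from lpadapt.lpball import LpShape, unit_ball_volume

    return Oracle(
        lambda x: float(x @ x) <= r2,
        n=n,
        name=f"ball{n}",
        batch_predicate=lambda pts: (pts**2).sum(axis=1) <= r2,
        true_volume=unit_ball_volume(LpShape(p=2.0, n=n)) * radius**n,
        bounding_box=np.stack([-radius * np.ones(n), radius * np.ones(n)], axis=1),
    )


@pytest.fixture
def disk_oracle():
    return make_disk_oracle()
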