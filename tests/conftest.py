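import numpy as np
import pytest

from ecgbnet.model_spec import NetworkSpec, UnitSpec, default_ecg_id_bnet, infer_shapes
from ecgbnet.reference_engine import Beat


@pytest.fixture(scope="session")
def default_spec():
    return default_ecg_id_bnet()


def small_spec(n_units=2, has_pool=False, in_length=180, kernel_size=3,
               n_classes=4):
    """A compact multiple-of-64 architecture for fast engine tests."""
    units = [UnitSpec(kind="conv", n_filters=64, in_channels=1,
                      in_length=in_length)]
    for _ in range(n_units - 2):
        units.append(UnitSpec(kind="conv", n_filters=64))
    if has_pool:
        units[-1].has_pool = True
        units[-1].pool_size = 2
    units.append(UnitSpec(kind="fc", n_filters=n_classes))
    return infer_shapes(NetworkSpec(units=units, kernel_size=kernel_size))


def random_small_spec(rng):
    """Draw a random packable architecture (used in equivalence sweeps)."""
    n_conv = int(rng.integers(1, 4))
    kernel = int(rng.integers(2, 9))
    units = []
    units.append(UnitSpec(kind="conv",
                          n_filters=int(rng.choice([64, 128])),
                          in_channels=1, in_length=180))
    for _ in range(n_conv - 1):
        units.append(UnitSpec(kind="conv",
                              n_filters=int(rng.choice([64, 128]))))
    units.append(UnitSpec(kind="fc", n_filters=int(rng.integers(2, 8))))
    spec = NetworkSpec(units=units, kernel_size=kernel)
    try:
        spec = infer_shapes(spec)
    except ValueError:
        return None
    # optionally pool the last conv unit when its length divides evenly
    last_conv = spec.units[-2]
    if rng.random() < 0.5 and last_conv.out_length % 2 == 0:
        last_conv.has_pool = True
        last_conv.pool_size = 2
        last_conv.out_length = None
        for u in spec.units:
            if u.kind == "fc":
                u.in_channels = None
        spec = infer_shapes(NetworkSpec(units=spec.units,
                                        kernel_size=spec.kernel_size))
    return spec


def random_beat(rng, subject_id=None):
    return Beat(rng.integers(-128, 128, 180).astype(np.int8),
                subject_id=subject_id)
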