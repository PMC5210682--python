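import numpy as np
import pytest

from fractodim import FDRecord

BENIGN = ("A", "F", "PT", "TA")
MALIGNANT = ("DC", "LC", "MC", "PC")


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_records(
    rng,
    n_per_class=100,
    mean_benign=1.80,
    mean_malignant=1.55,
    sd=0.05,
    magnification="40x",
):
    """Gaussian fd feature tables without rendering any images."""
    records = []
    for label, mean, subtypes in (
        ("benign", mean_benign, BENIGN),
        ("malignant", mean_malignant, MALIGNANT),
    ):
        fds = rng.normal(mean, sd, n_per_class)
        for i, fd in enumerate(fds):
            records.append(
                FDRecord(
                    image_id=f"{label}{i}",
                    magnification=magnification,
                    label=label,
                    subtype=subtypes[i % 4],
                    fd=float(fd),
                )
            )
    return records


@pytest.fixture
def gaussian_records(rng):
    return make_records(rng)
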