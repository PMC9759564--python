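"""Shared fixtures: synthetic datasets and UCI-dialect-format files.

All file fixtures are generated programmatically; the dialect files are
synthetic stand-ins that follow the WBC/WDBC layouts with known row,
missing-cell and class counts.
"""

import numpy as np
import pytest

from tab2pix import SimSpec, minmax_normalize, simulate

#: (rows, missing cells, benign count, malignant count) of the synthetic
#: WBC-format fixture below
WBC_FIXTURE_COUNTS = dict(n=40, missing=5, benign=26, malignant=14)
WDBC_FIXTURE_COUNTS = dict(n=30, missing=0, benign=19, malignant=11)


@pytest.fixture()
def small_dataset():
    """Sixty rows, six features, strongly separable, no missing cells."""
    return simulate(SimSpec(n=60, d=6, separation=3.0, seed=7))


@pytest.fixture()
def normalized_dataset(small_dataset):
    return minmax_normalize(small_dataset)


@pytest.fixture()
def wbc_format_file(tmp_path):
    """Synthetic file in the WBC layout: ID, 9 integer features, class 2/4.

    Five cells in five distinct rows carry the ``?`` missing marker.
    """
    rng = np.random.default_rng(11)
    counts = WBC_FIXTURE_COUNTS
    labels = [1] * counts["benign"] + [0] * counts["malignant"]
    rng.shuffle(labels)
    missing_rows = set(rng.choice(counts["n"], size=counts["missing"],
                                  replace=False).tolist())
    lines = []
    for i, lab in enumerate(labels):
        feats = rng.integers(1, 11, size=9).astype(object)
        if i in missing_rows:
            feats[int(rng.integers(0, 9))] = "?"
        code = 2 if lab == 1 else 4
        lines.append(",".join([str(1000000 + i)]
                              + [str(v) for v in feats] + [str(code)]))
    path = tmp_path / "synthetic_wbc.data"
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture()
def wdbc_format_file(tmp_path):
    """Synthetic file in the WDBC layout: ID, diagnosis M/B, 30 reals."""
    rng = np.random.default_rng(13)
    counts = WDBC_FIXTURE_COUNTS
    labels = [1] * counts["benign"] + [0] * counts["malignant"]
    rng.shuffle(labels)
    lines = []
    for i, lab in enumerate(labels):
        feats = rng.uniform(0.01, 30.0, size=30)
        code = "B" if lab == 1 else "M"
        lines.append(",".join([str(842000 + i), code]
                              + [f"{v:.4f}" for v in feats]))
    path = tmp_path / "synthetic_wdbc.data"
    path.write_text("\n".join(lines) + "\n")
    return path
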