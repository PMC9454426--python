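import numpy as np
import pytest

from msidl import BinningScheme, CoreAnnotation, MSIDataset, SyntheticConfig, generate_tma


@pytest.fixture(scope="session")
def small_cfg():
    """Fast three-class TMA on a short axis (seconds to generate/train on)."""
    return SyntheticConfig(
        scheme=BinningScheme(590.0, 610.0, 0.010),
        cores_per_class={"A": 6, "B": 6, "Matrix": 3},
        markers_per_class=3,
        n_background_peaks=10,
        n_matrix_peaks=40,
        core_radius=2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_tma(small_cfg):
    return generate_tma(small_cfg)


def make_flat_dataset(class_counts: dict[str, int], n_bins: int = 8,
                      seed: int = 0, scheme: BinningScheme | None = None) -> MSIDataset:
    """Hand-built dataset: one single-pixel-column core per class with the
    requested number of pixels, random non-negative intensities."""
    rng = np.random.default_rng(seed)
    scheme = scheme or BinningScheme(100.0, 100.0 + n_bins, 1.0)
    coords, core_ids, annotations = [], [], []
    y = 0
    for cls, n in class_counts.items():
        core = f"{cls}_core"
        pix = [(x, y) for x in range(n)]
        annotations.append(CoreAnnotation(core, cls, frozenset(pix)))
        coords.extend(pix)
        core_ids.extend([core] * n)
        y += 1
    total = len(coords)
    ds = MSIDataset(
        scheme=scheme,
        intensities=rng.random((total, scheme.n_bins)).astype(np.float32),
        coords=np.asarray(coords, dtype=np.int64),
        core_ids=np.asarray(core_ids, dtype=object),
        annotations=annotations,
        class_order=sorted(class_counts),
    )
    ds.validate()
    return ds
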