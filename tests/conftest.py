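import numpy as np
import pytest
from skimage.draw import disk as skdisk, ellipse as skellipse

from nucrank import synthgen
from nucrank.core_io import ImageRecord, candidate_from_mask


def disk_mask(radius: int, pad: int = 5) -> np.ndarray:
    side = 2 * radius + 2 * pad + 1
    m = np.zeros((side, side), dtype=bool)
    rr, cc = skdisk((side // 2, side // 2), radius)
    m[rr, cc] = True
    return m


def ellipse_mask(a: int, b: int, pad: int = 5) -> np.ndarray:
    h, w = 2 * a + 2 * pad + 1, 2 * b + 2 * pad + 1
    m = np.zeros((h, w), dtype=bool)
    rr, cc = skellipse(h // 2, w // 2, a, b)
    m[rr, cc] = True
    return m


def rough_blob_mask(radius: float, seed: int, roughness: float = 0.12,
                    ) -> np.ndarray:
    rng = np.random.default_rng(seed)
    side = int(2.4 * radius) + 20
    shape = synthgen._random_shape(rng, (side / 2, side / 2), radius,
                                   (1.0, 1.8), roughness)
    return synthgen._render_shape(shape, (side, side))


def make_obj(mask: np.ndarray, oid: str = "obj", image_id: str = "img"):
    return candidate_from_mask(mask, oid, image_id)


def flat_image(shape, value=50.0, image_id="img"):
    return ImageRecord(image_id, "S01", "S01C01",
                       np.full(shape, value, dtype=float))


@pytest.fixture(scope="session")
def separable_cohort():
    """Two subjects x two cores, 400 candidate slots, two cleanly
    separated candidate classes (intact nuclei vs debris blobs)."""
    return synthgen.generate_cohort(synthgen.separable_spec(seed=11))


@pytest.fixture(scope="session")
def separable_features(separable_cohort):
    from nucrank import features
    co = separable_cohort
    table = features.extract_all(co.candidates_by_image(),
                                 co.images_by_id(), co.assigned_spots())
    X = table.set_index("object_id")
    y = co.labels().reindex(X.index)
    prov = co.provenance().set_index("object_id").reindex(X.index)
    return X, y, prov
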