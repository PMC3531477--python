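import math

import pytest

from centrotrace.quantify import segment_spots
from centrotrace.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def s5_batch():
    """25 seeded S5 spermatocyte scenes (100 nuclei) with segmentations."""
    batch = []
    for seed in range(25):
        scene = generate_scene(SceneConfig(stage="spermatocyte_S5", n_nuclei=4, seed=seed))
        regions = segment_spots(scene.gfp_image, nucleus_labels=scene.nucleus_masks)
        batch.append((scene, regions))
    return batch


def nearest_region(regions, center):
    """Index of the region whose centroid is closest to a ground-truth spot."""
    return min(range(len(regions)), key=lambda i: math.dist(regions[i].centroid, center))
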