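import numpy as np
import pytest

from duplexmut import generate_reference_panel
from duplexmut.panel import TargetRegion
from duplexmut.variants import VariantCall


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel():
    return generate_reference_panel(n_targets=3, length=300, seed=11)


@pytest.fixture
def toy_target():
    """A 60-bp coding target with a known sequence (frame 0)."""
    seq = "ATGACCGTACGTTAGCCATGCATTACGGATCCGTAAGCTTGCAATGCCGTAGCTAACGTT"
    return TargetRegion(
        name="toy", contig="toy", start=0, end=60, sequence=seq,
        transcribed=True, transcribed_strand="-", frame_offset=0,
    )


def make_call(target="toy", position=5, ref="C", alt="T", alt_count=1,
              depth=1000, sample="s1", tissue="", treatment="",
              germline=False, clonal=False):
    return VariantCall(
        target=target, position=position, ref=ref, alt=alt,
        alt_count=alt_count, depth=depth, sample=sample, tissue=tissue,
        treatment=treatment, germline=germline, clonal=clonal,
    )


@pytest.fixture
def call_factory():
    return make_call


def brute_force_wpgma(matrix):
    """Independent small-n WPGMA oracle on cosine distance.

    Maintains the full distance matrix; at each step merges the closest
    pair and sets the new cluster's distance to any other cluster as the
    plain average of its two children's distances. Returns the sorted
    merge heights.
    """
    def cosine_dist(u, v):
        return 1 - (u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))

    n = len(matrix)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = cosine_dist(matrix[i], matrix[j])
    active = list(range(n))
    next_id = n
    heights = []
    while len(active) > 1:
        h, a, b = min(
            (dist[(min(a, b), max(a, b))], a, b)
            for i, a in enumerate(active)
            for b in active[i + 1 :]
        )
        heights.append(h)
        for c in active:
            if c in (a, b):
                continue
            da = dist[(min(a, c), max(a, c))]
            db = dist[(min(b, c), max(b, c))]
            dist[(min(next_id, c), max(next_id, c))] = (da + db) / 2
        active = [c for c in active if c not in (a, b)] + [next_id]
        next_id += 1
    return sorted(heights)


@pytest.fixture
def wpgma_oracle():
    return brute_force_wpgma
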