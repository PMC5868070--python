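"""Shared fixtures: synthetic leaves and their pipeline results.

Everything is generated programmatically at test time; the synthetic
generator's ground truth is the reference for every downstream stage.
"""

import warnings

import numpy as np
import pytest

from leafdissect.pipeline import analyze_mask
from leafdissect.synthetic import SyntheticLeafSpec, generate_leaf

# scikit-image deprecation chatter is not under test
warnings.filterwarnings("ignore", category=FutureWarning)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    union = np.logical_or(a, b).sum()
    return float(np.logical_and(a, b).sum() / union) if union else 1.0


def best_jaccard(detected: np.ndarray, truth_masks) -> float:
    """Jaccard of a detected leaflet against its best-matching truth mask."""
    return max(jaccard(detected, tm) for tm in truth_masks)


@pytest.fixture(scope="session")
def two_pair_truth():
    """Mid-sized reference leaf: 2 lateral pairs + terminal (5 leaflets)."""
    return generate_leaf(SyntheticLeafSpec(n_lateral_pairs=2, seed=1))


@pytest.fixture(scope="session")
def two_pair_result(two_pair_truth):
    return analyze_mask(two_pair_truth.mask)


@pytest.fixture(scope="session")
def three_pair_truth():
    return generate_leaf(SyntheticLeafSpec(n_lateral_pairs=3, seed=7))


@pytest.fixture(scope="session")
def three_pair_result(three_pair_truth):
    return analyze_mask(three_pair_truth.mask)


@pytest.fixture(scope="session")
def simple_leaf_truth():
    """Degenerate case: petiole + terminal blade only."""
    return generate_leaf(
        SyntheticLeafSpec(
            n_lateral_pairs=0,
            petiole_length=70,
            terminal_leaflet_semi_axes=(30.0, 18.0),
            seed=3,
        )
    )
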