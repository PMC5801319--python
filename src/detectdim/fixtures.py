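"""Small deterministic fixture files for tests and demonstrations.

Everything is generated programmatically from a seed; the manifest records
oracle values (reference-path conditional covariances, the exhaustively
maximized partition of a planted block matrix) computed at generation time
so that downstream checks can re-derive and compare them.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .conditional_covariance import ccov_pair
from .detect import detect_index, maximize_partition
from .simulate import ResponseMatrix

__all__ = ["planted_block_ccov", "two_bank_exam", "make_fixtures"]


def planted_block_ccov(
    n_items: int = 6, within: float = 0.01, cross: float = -0.01
) -> tuple[np.ndarray, np.ndarray]:
    """Conditional-covariance matrix with two planted item blocks.

    Returns the matrix (NaN diagonal) and the true block labels
    (first half 0, second half 1).
    """
    half = n_items // 2
    labels = np.repeat([0, 1], (half, n_items - half))
    values = np.where(labels[:, None] == labels[None, :], within, cross)
    values = values.astype(float)
    np.fill_diagonal(values, np.nan)
    return values, labels


def two_bank_exam(
    rng: np.random.Generator,
    n_examinees: int = 300,
    items_per_bank: int = 10,
    discrimination: float = 1.7,
) -> tuple[ResponseMatrix, np.ndarray]:
    """Synthetic two-subject exam from two independent unidimensional banks.

    Each bank has its own latent ability, independent of the other's, so a
    whole-test DETECT run should split the items along the bank boundary.
    Returns the response matrix and the true bank label per item.
    """
    n_items = 2 * items_per_bank
    theta = rng.standard_normal((n_examinees, 2))
    beta = rng.normal(0.0, 0.5, size=n_items)
    bank = np.repeat([0, 1], items_per_bank)
    logits = discrimination * theta[:, bank] + beta
    probs = 1.0 / (1.0 + np.exp(-logits))
    scores = (rng.random(probs.shape) < probs).astype(np.int8)
    return ResponseMatrix(scores=scores), bank


def _nondegenerate_binary(rng, shape):
    while True:
        scores = (rng.random(shape) < 0.5).astype(np.int8)
        means = scores.mean(axis=0)
        if ((means > 0) & (means < 1)).all():
            return scores


def make_fixtures(out_dir, seed: int) -> dict:
    """Write the toy fixture files and their oracle manifest; returns manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # 8 examinees x 4 items: small enough for hand/enumeration checks.
    small = _nondegenerate_binary(rng, (8, 4))
    np.savetxt(out_dir / "ccov_oracle_8x4.csv", small, fmt="%d", delimiter=",")
    pairs = {}
    for i in range(4):
        for j in range(i + 1, 4):
            pairs[f"{i},{j}"] = ccov_pair(small, i, j, min_group=2)

    planted, blocks = planted_block_ccov()
    np.savetxt(out_dir / "planted_blocks_ccov.csv", planted, delimiter=",")
    best = maximize_partition(planted, method="exhaustive")
    planted_info = {
        "true_blocks": blocks.tolist(),
        "best_partition": best.tolist(),
        "dstar": detect_index(planted, best),
    }

    parse_toy = _nondegenerate_binary(rng, (3, 4))
    np.savetxt(out_dir / "parse_toy_3x4.csv", parse_toy, fmt="%d", delimiter=",")

    exam, bank = two_bank_exam(rng)
    exam.to_csv(out_dir / "exam_two_banks.csv")
    (out_dir / "exam_two_banks_blueprint.yaml").write_text(
        "subjects:\n  Bank A: 10\n  Bank B: 10\n"
    )

    manifest = {
        "seed": seed,
        "ccov_oracle_8x4": {"shape": [8, 4], "min_group": 2, "ccov_pairs": pairs},
        "planted_blocks_ccov": planted_info,
        "parse_toy_3x4": {"shape": [3, 4]},
        "exam_two_banks": {
            "shape": list(exam.scores.shape),
            "true_banks": bank.tolist(),
        },
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
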