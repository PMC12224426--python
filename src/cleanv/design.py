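"""Between-image relatedness matrices for reliability, twin and custom designs.

The variance-component score statistic is a quadratic form of null-model
residuals with an N x N kernel ``K`` that encodes which images are expected
to covary: same-subject scans in a test-retest study (entries 1 within a
subject, 0 across), expected genetic sharing in a twin study (1 for
monozygotic co-twins, 0.5 for dizygotic, 0 otherwise), or an arbitrary
genetic relationship matrix in pedigree studies.

Built-in designs keep a unit diagonal. Replacing ``K`` by ``K - I`` shifts
every score statistic by the permutation-invariant constant ``d'd`` and
therefore leaves all permutation-standardized statistics unchanged; this
equivalence is covered by a unit test, so the literal "same subject includes
i = i*" rule is kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

PSD_RTOL = 1e-8  # relative to the spectral norm


class DesignError(ValueError):
    """Raised for malformed study-design inputs."""


@dataclass
class RelatednessMatrix:
    """N x N symmetric PSD kernel of expected between-image covariance."""

    K: np.ndarray
    design_label: str  # test_retest | twin | custom

    @property
    def n_images(self) -> int:
        return self.K.shape[0]

    def has_related_pairs(self) -> bool:
        """True if any off-diagonal entry is nonzero."""
        off = self.K - np.diag(np.diag(self.K))
        return bool(np.any(off != 0))


def _check_psd(K: np.ndarray, label: str) -> None:
    eigmin = float(np.linalg.eigvalsh(K).min())
    norm = float(np.linalg.norm(K, 2)) or 1.0
    if eigmin < -PSD_RTOL * norm:
        raise DesignError(
            f"{label} kinship matrix is not positive semidefinite "
            f"(smallest eigenvalue {eigmin:.3g})"
        )


def kinship_test_retest(subject_ids) -> RelatednessMatrix:
    """Kernel for a test-retest design: 1 within subject, 0 across.

    ``subject_ids`` is a length-N sequence of labels, one per image.
    Diagonal entries are 1. Warns when every subject has a single image,
    since the statistic then has no between-image signal to detect.
    """
    ids = np.asarray(subject_ids)
    if ids.ndim != 1 or ids.size == 0:
        raise DesignError("subject_ids must be a nonempty 1-d sequence")
    K = (ids[:, None] == ids[None, :]).astype(float)
    _, counts = np.unique(ids, return_counts=True)
    if counts.max() < 2:
        warnings.warn(
            "all subjects have a single image: the relatedness kernel is the "
            "identity and the test is degenerate",
            stacklevel=2,
        )
    return RelatednessMatrix(K=K, design_label="test_retest")


def kinship_twins(pair_ids, zygosity) -> RelatednessMatrix:
    """Kernel for a twin design: MZ co-twins 1, DZ co-twins 0.5, else 0.

    ``pair_ids`` labels each image's twin pair (each label appears exactly
    twice); ``zygosity`` gives 'MZ' or 'DZ' per image (consistent within a
    pair).
    """
    pair = np.asarray(pair_ids)
    zyg = np.asarray([str(z).upper() for z in np.asarray(zygosity)])
    if pair.shape != zyg.shape or pair.ndim != 1:
        raise DesignError("pair_ids and zygosity must be 1-d and equal length")
    bad = set(zyg) - {"MZ", "DZ"}
    if bad:
        raise DesignError(f"unknown zygosity codes: {sorted(bad)} (expected MZ/DZ)")
    labels, counts = np.unique(pair, return_counts=True)
    wrong = labels[counts != 2]
    if wrong.size:
        raise DesignError(
            f"each pair id must appear exactly twice; offending ids: "
            f"{wrong[:5].tolist()}"
        )
    N = pair.size
    K = np.eye(N)
    for lab in labels:
        idx = np.flatnonzero(pair == lab)
        z = set(zyg[idx])
        if len(z) != 1:
            raise DesignError(f"pair {lab!r} has inconsistent zygosity {sorted(z)}")
        coef = 1.0 if z.pop() == "MZ" else 0.5
        i, j = idx
        K[i, j] = K[j, i] = coef
    return RelatednessMatrix(K=K, design_label="twin")


def custom_kinship(K: np.ndarray) -> RelatednessMatrix:
    """Validate an arbitrary relatedness matrix (e.g. a GRM).

    Symmetrizes via (K + K') / 2 and rejects matrices whose smallest
    eigenvalue is below -1e-8 times the spectral norm.
    """
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise DesignError(f"kinship matrix must be square, got shape {K.shape}")
    K = (K + K.T) / 2.0
    _check_psd(K, "custom")
    return RelatednessMatrix(K=K, design_label="custom")


def load_custom_kinship(path, image_ids=None) -> RelatednessMatrix:
    """Read a square delimited kinship matrix with id header row/column.

    If ``image_ids`` is given, rows/columns are reordered to match it.
    """
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if df.shape[0] != df.shape[1]:
        raise DesignError(
            f"kinship file must be square, got {df.shape[0]} x {df.shape[1]}"
        )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if image_ids is not None:
        ids = [str(i) for i in image_ids]
        missing = set(ids) - set(df.index)
        if missing:
            raise DesignError(f"kinship file missing image ids: {sorted(missing)[:5]}")
        df = df.loc[ids, ids]
    return custom_kinship(df.to_numpy(dtype=float))
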