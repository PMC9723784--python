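"""Tanimoto similarity, the PDCC x LDCC similarity matrix, and thresholding.

The Tanimoto coefficient between two bit-set fingerprints A and B is
|A n B| / |A u B|, the standard 2-D similarity measure in cheminformatics.
Thresholding uses the unrounded fraction; percentages are presentation
only.  The default edge-inclusion rule is similarity >= 0.65, with the
strict ``>`` variant available through the ``inclusive`` flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chem_core import Molecule
from .fingerprints import Fingerprint, FingerprintConfig, FingerprintError, compute_fingerprint

__all__ = [
    "tanimoto",
    "SimilarityMatrix",
    "SimilarityEdge",
    "similarity_matrix",
    "threshold_edges",
    "write_matrix_tsv",
    "read_matrix_tsv",
]

logger = logging.getLogger(__name__)

DEFAULT_THETA = 0.65


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tanimoto coefficient |A n B| / |A u B| of two fingerprints.

    Both fingerprints must come from the identical configuration.  Two empty
    bit sets yield 0.0 (with a warning) rather than an undefined value.
    """
    if a.config != b.config:
        raise ValueError(
            f"fingerprint config mismatch: {a.config} vs {b.config}"
        )
    union = len(a.bits | b.bits)
    if union == 0:
        logger.warning(
            "tanimoto of two empty fingerprints (%s, %s): returning 0.0",
            a.molecule_name,
            b.molecule_name,
        )
        return 0.0
    return len(a.bits & b.bits) / union


@dataclass(frozen=True)
class SimilarityEdge:
    """One above-threshold PDCC-LDCC compound pair."""

    pdcc_id: str
    ldcc_id: str
    similarity: float


@dataclass
class SimilarityMatrix:
    """Rectangular PDCC (rows) x LDCC (columns) Tanimoto matrix."""

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    fp_config: FingerprintConfig = field(default_factory=FingerprintConfig)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_ids), len(self.col_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.col_ids)} cols"
            )
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise ValueError("similarity values must lie in [0, 1]")

    def lookup(self, pdcc_id: str, ldcc_id: str) -> float:
        return float(
            self.values[self.row_ids.index(pdcc_id), self.col_ids.index(ldcc_id)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)


def similarity_matrix(
    pdcc: list[tuple[str, Molecule]],
    ldcc: list[tuple[str, Molecule]],
    cfg: FingerprintConfig,
) -> SimilarityMatrix:
    """All-pairs Tanimoto matrix between PDCC rows and LDCC columns.

    Every molecule is fingerprinted once under ``cfg``; molecules that fail
    fingerprinting abort the computation with an error naming every
    offending id.
    """
    if not pdcc or not ldcc:
        raise ValueError("both compound lists must be non-empty")
    ids = [i for i, _ in pdcc] + [i for i, _ in ldcc]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise ValueError(f"duplicate compound id(s): {sorted(dupes)}")

    failures: list[str] = []
    fps: dict[str, Fingerprint] = {}
    for cid, mol in [*pdcc, *ldcc]:
        try:
            fps[cid] = compute_fingerprint(mol, cfg)
        except FingerprintError as exc:
            failures.append(f"{cid}: {exc}")
    if failures:
        raise FingerprintError(
            "fingerprinting failed for "
            + str(len(failures))
            + " compound(s): "
            + "; ".join(failures)
        )

    values = np.array(
        [[tanimoto(fps[p], fps[l]) for l, _ in ldcc] for p, _ in pdcc]
    )
    return SimilarityMatrix(
        row_ids=[i for i, _ in pdcc],
        col_ids=[i for i, _ in ldcc],
        values=values,
        fp_config=cfg,
    )


def threshold_edges(
    m: SimilarityMatrix, theta: float = DEFAULT_THETA, inclusive: bool = True
) -> list[SimilarityEdge]:
    """Edges for every pair at or above the similarity threshold.

    ``inclusive`` selects >= (default, the edge-inclusion rule) versus
    strict >.  Output order is deterministic row-major.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    edges: list[SimilarityEdge] = []
    for i, p in enumerate(m.row_ids):
        for j, l in enumerate(m.col_ids):
            v = float(m.values[i, j])
            if (v >= theta) if inclusive else (v > theta):
                edges.append(SimilarityEdge(p, l, v))
    return edges


def write_matrix_tsv(m: SimilarityMatrix, path) -> None:
    """Export: first row LDCC ids, first column PDCC ids, 4-decimal cells."""
    m.to_frame().to_csv(path, sep="\t", float_format="%.4f", index_label="pdcc_id")


def read_matrix_tsv(path, fp_config: FingerprintConfig | None = None) -> SimilarityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(
        row_ids=[str(i) for i in df.index],
        col_ids=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        fp_config=fp_config or FingerprintConfig(),
    )
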