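"""Dense matrix persistence: tab-separated values with protein-ID headers.

One format serves every dense matrix in the pipeline (evolved matrix EA,
transition matrix T, score matrix P, feature kernels): the first row and
first column carry the protein IDs, the body is tab-separated floats.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


def save_matrix_tsv(
    values: np.ndarray, node_order: Sequence[str], path: str | Path
) -> None:
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=list(node_order), columns=list(node_order))
    df.to_csv(path, sep="\t", float_format="%.10g")


def load_matrix_tsv(path: str | Path) -> tuple[np.ndarray, tuple[str, ...]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"matrix file not found: {path}")
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column IDs differ")
    return df.to_numpy(dtype=float), tuple(str(c) for c in df.columns)
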