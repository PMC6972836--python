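"""Reading and writing community matrices and run configurations.

Community matrices travel as delimited text: a header row of species labels,
a first column of site labels, one row per sample unit.  The delimiter is
auto-detected among comma and tab unless given explicitly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .model_core import CommunityMatrix
from .samplers import MCMCSettings

__all__ = ["read_community", "write_community", "RunConfig"]


def _detect_delimiter(path) -> str:
    first = Path(path).open().readline()
    return "\t" if first.count("\t") >= first.count(",") else ","


def read_community(
    path,
    family: str,
    K: Optional[int] = None,
    delimiter: Optional[str] = None,
    transpose: bool = False,
) -> CommunityMatrix:
    """Load a delimited site-by-species table as a validated CommunityMatrix.

    ``transpose`` accommodates species-by-site files.  Validation errors name
    the offending cell by its (0-based) row and column in the matrix.
    """
    sep = delimiter or _detect_delimiter(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.isna().any().any():
        i, j = np.argwhere(df.isna().to_numpy())[0]
        raise ValueError(f"missing or ragged entry at row {i}, column {j} of {path}")
    if transpose:
        df = df.T
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cell in {path}: {exc}") from exc
    return CommunityMatrix(
        values,
        family=family,
        n_levels=K,
        site_labels=[str(s) for s in df.index],
        species_labels=[str(s) for s in df.columns],
    )


def write_community(Y: CommunityMatrix, path, delimiter: str = ",") -> None:
    """Write a CommunityMatrix back to delimited text (round-trip exact)."""
    df = pd.DataFrame(Y.values, index=list(Y.site_labels), columns=list(Y.species_labels))
    df.index.name = "site"
    df.to_csv(path, sep=delimiter)


@dataclass
class RunConfig:
    """Effective configuration of one fit, written alongside its outputs."""

    input_path: str = ""
    family: str = "binary"
    K: Optional[int] = None
    q: int = 2
    mu_alpha: float = 0.0
    v_alpha: float = 1.0
    mu_beta: float = 0.0
    v_beta: float = 1.0
    omega_prior_scale: float = float(np.sqrt(20.0))
    mcmc: MCMCSettings = field(default_factory=MCMCSettings)
    output_dir: str = "."
    seed: int = 0
    transpose: bool = False
    delimiter: Optional[str] = None

    def save(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = json.load(fh)
        d["mcmc"] = MCMCSettings(**d["mcmc"])
        return cls(**d)
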