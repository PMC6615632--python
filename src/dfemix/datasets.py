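"""Core data containers for the recombinant-line (RL) crossing design.

An RL dataset holds, for one MA-line cross or a merged set of crosses:

* ``M`` — an ``n_b x n_m`` 0/1 matrix of mutation presence per observation,
* ``F`` — an ``n_b x n_f`` 0/1 matrix of two-level fixed-effect markers
  (mating type, introgressed non-focal-background regions),
* ``plate`` — growth-assay plate index per observation,
* ``line`` — MA-line index per observation (merged analyses fit one overall
  mean per MA line),
* ``y`` — the phenotype (maximum growth rate) per observation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass
class RLDataset:
    """Genotype/phenotype data for a recombinant-line crossing experiment."""

    y: np.ndarray
    M: np.ndarray
    F: np.ndarray | None = None
    plate: np.ndarray | None = None
    line: np.ndarray | None = None
    mutation_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.M = np.asarray(self.M)
        if self.M.ndim != 2:
            raise ValueError("M must be a 2-D matrix")
        n_b = self.y.shape[0]
        if self.M.shape[0] != n_b:
            raise ValueError(
                f"M has {self.M.shape[0]} rows but y has {n_b} observations"
            )
        if self.F is None:
            self.F = np.zeros((n_b, 0), dtype=np.int8)
        self.F = np.asarray(self.F)
        if self.F.shape[0] != n_b:
            raise ValueError("F row count does not match y")
        if self.plate is not None:
            # plate=None means no plate structure (no plate random effect)
            self.plate = np.asarray(self.plate, dtype=np.int64).ravel()
            if self.plate.shape[0] != n_b:
                raise ValueError("plate index length does not match y")
        if self.line is None:
            self.line = np.zeros(n_b, dtype=np.int64)
        self.line = np.asarray(self.line, dtype=np.int64).ravel()
        if self.line.shape[0] != n_b:
            raise ValueError("line index length does not match y")
        for mat, name in ((self.M, "M"), (self.F, "F")):
            if mat.size and not np.isin(mat, (0, 1)).all():
                raise ValueError(f"{name} entries must be 0 or 1")
        if self.mutation_ids is None:
            self.mutation_ids = [f"mut{j:04d}" for j in range(self.M.shape[1])]
        if len(self.mutation_ids) != self.M.shape[1]:
            raise ValueError("mutation_ids length does not match M columns")

    @property
    def n_b(self) -> int:
        return self.y.shape[0]

    @property
    def n_m(self) -> int:
        return self.M.shape[1]

    @property
    def n_f(self) -> int:
        return self.F.shape[1]

    @property
    def n_p(self) -> int:
        if self.plate is None or not self.n_b:
            return 0
        return int(self.plate.max()) + 1

    @property
    def n_lines(self) -> int:
        return int(self.line.max()) + 1 if self.n_b else 0

    # ------------------------------------------------------------------ I/O

    def to_dir(self, path: str | Path, truth: dict | None = None) -> None:
        """Write the three-file TSV contract plus a JSON sidecar.

        ``genotypes.tsv`` holds the 0/1 mutation matrix, ``observations.tsv``
        the per-observation fixed effects, plate, line and phenotype, and
        ``meta.json`` any scenario parameters passed in ``truth``.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        geno = pd.DataFrame(self.M, columns=self.mutation_ids)
        geno.insert(0, "obs", np.arange(self.n_b))
        geno.to_csv(path / "genotypes.tsv", sep="\t", index=False)
        obs = pd.DataFrame({"obs": np.arange(self.n_b), "line": self.line})
        if self.plate is not None:
            obs["plate"] = self.plate
        obs["phenotype"] = self.y
        for j in range(self.n_f):
            obs[f"fixed{j}"] = self.F[:, j]
        obs.to_csv(path / "observations.tsv", sep="\t", index=False)
        meta = {"n_b": self.n_b, "n_m": self.n_m, "n_f": self.n_f}
        if truth is not None:
            meta.update(
                {
                    k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in truth.items()
                }
            )
        (path / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def from_dir(cls, path: str | Path) -> "RLDataset":
        path = Path(path)
        geno = pd.read_csv(path / "genotypes.tsv", sep="\t")
        obs = pd.read_csv(path / "observations.tsv", sep="\t")
        mut_cols = [c for c in geno.columns if c != "obs"]
        fixed_cols = [c for c in obs.columns if c.startswith("fixed")]
        return cls(
            y=obs["phenotype"].to_numpy(),
            M=geno[mut_cols].to_numpy(dtype=np.int8),
            F=obs[fixed_cols].to_numpy(dtype=np.int8) if fixed_cols else None,
            plate=obs["plate"].to_numpy() if "plate" in obs else None,
            line=obs["line"].to_numpy(),
            mutation_ids=mut_cols,
        )

    @classmethod
    def from_merged_table(
        cls,
        df: pd.DataFrame,
        phenotype_col: str = "phenotype",
        plate_col: str = "plate",
        line_col: str | None = "line",
        mutation_prefix: str = "mut",
        fixed_prefix: str = "fixed",
    ) -> "RLDataset":
        """Build a dataset from a single merged table (one row per observation).

        Mutation and fixed-effect columns are identified by prefix.  Rows with
        missing genotypes are dropped, mirroring the rule that merged analyses
        exclude any RL with one or more missing genotypes.
        """
        mut_cols = [c for c in df.columns if c.startswith(mutation_prefix)]
        fixed_cols = [c for c in df.columns if c.startswith(fixed_prefix)]
        df = df.dropna(subset=mut_cols + [phenotype_col])
        plate = pd.factorize(df[plate_col])[0] if plate_col in df else None
        line = (
            pd.factorize(df[line_col])[0]
            if line_col is not None and line_col in df
            else None
        )
        return cls(
            y=df[phenotype_col].to_numpy(),
            M=df[mut_cols].to_numpy(dtype=np.int8),
            F=df[fixed_cols].to_numpy(dtype=np.int8) if fixed_cols else None,
            plate=plate,
            line=line,
            mutation_ids=mut_cols,
        )
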