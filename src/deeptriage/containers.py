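"""Core data containers: expression matrices and gene-set collections.

An :class:`ExpressionMatrix` is a samples x features grid of non-negative
values (raw counts or normalised counts) with unique sample and feature
identifiers. A :class:`GeneSetCollection` is an ordered mapping from set id
(e.g. a GO term or KEGG pathway accession) to a description and a set of
member gene ids, read from / written to GMT files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "GeneSet", "GeneSetCollection"]


def _check_unique(ids: list[str], kind: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dupes = sorted({i for i in ids if i in seen or seen.add(i)})  # type: ignore[func-returns-value]
        raise ValueError(f"duplicate {kind} ids: {dupes[:5]}")


@dataclass
class ExpressionMatrix:
    """Samples x features matrix of non-negative, finite values.

    Parameters
    ----------
    sample_ids : list of str
        Unique row identifiers.
    feature_ids : list of str
        Unique column identifiers (genes or annotation sets).
    values : ndarray of shape (n_samples, n_features)
        Non-negative expression values.
    """

    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.feature_ids)} features"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.feature_ids, "feature")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("values contain negative entries")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            sample_ids=[str(i) for i in frame.index],
            feature_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )

    @classmethod
    def read_tsv(cls, path: str | Path, transposed: bool = False, sep: str | None = None) -> "ExpressionMatrix":
        """Read a matrix from TSV/CSV.

        Default dialect: first column holds sample ids, header row holds
        feature ids. With ``transposed=True`` the file stores features as
        rows and samples as columns.
        """
        path = Path(path)
        if sep is None:
            sep = "," if path.suffix.lower() == ".csv" else "\t"
        frame = pd.read_csv(path, sep=sep, index_col=0)
        if transposed:
            frame = frame.T
        return cls.from_frame(frame)

    def to_tsv(self, path: str | Path, float_format: str = "%.10g") -> None:
        self.to_frame().to_csv(path, sep="\t", float_format=float_format)

    def subset_samples(self, ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(ids)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        rows = [pos[s] for s in ids]
        return ExpressionMatrix(ids, list(self.feature_ids), self.values[rows])


@dataclass(frozen=True)
class GeneSet:
    description: str
    members: frozenset[str]


@dataclass
class GeneSetCollection:
    """Ordered mapping from set id to (description, member gene ids)."""

    entries: dict[str, GeneSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, gs in self.entries.items():
            if not gs.members:
                raise ValueError(f"gene set {set_id!r} is empty")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __contains__(self, set_id: str) -> bool:
        return set_id in self.entries

    def __getitem__(self, set_id: str) -> GeneSet:
        return self.entries[set_id]

    def members(self, set_id: str) -> frozenset[str]:
        return self.entries[set_id].members

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]], descriptions: Mapping[str, str] | None = None) -> "GeneSetCollection":
        entries = {}
        for set_id, genes in mapping.items():
            desc = (descriptions or {}).get(set_id, "")
            entries[str(set_id)] = GeneSet(desc, frozenset(str(g) for g in genes))
        return cls(entries)

    @classmethod
    def read_gmt(cls, path: str | Path) -> "GeneSetCollection":
        """Read a GMT file: ``set_id<TAB>description<TAB>gene1<TAB>gene2...``.

        Duplicate gene ids within a line are deduplicated; duplicate set ids
        raise an error.
        """
        entries: dict[str, GeneSet] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip():
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise ValueError(f"{path}:{lineno}: GMT line needs id, description and >=1 gene")
                set_id, desc = parts[0], parts[1]
                genes = frozenset(g for g in parts[2:] if g)
                if set_id in entries:
                    raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
                if not genes:
                    raise ValueError(f"{path}:{lineno}: set {set_id!r} has no genes")
                entries[set_id] = GeneSet(desc, genes)
        return cls(entries)

    def write_gmt(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for set_id, gs in self.entries.items():
                genes = "\t".join(sorted(gs.members))
                fh.write(f"{set_id}\t{gs.description}\t{genes}\n")
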