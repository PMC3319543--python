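"""Core in-memory containers shared across the pipeline.

Conventions: expression matrices are stored samples-as-rows; class labels
are binary with 1 = positive (tumor) and 0 = negative (normal); edge tables
are undirected with duplicate pairs collapsed to the maximum confidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

POSITIVE_TOKENS = frozenset({"1", "pos", "positive", "tumor", "tumour", "case"})
NEGATIVE_TOKENS = frozenset({"0", "neg", "negative", "normal", "control"})


def parse_label(token: str | int | float) -> int:
    """Map a label token to 1 (positive/tumor) or 0 (negative/normal)."""
    s = str(token).strip().lower()
    if s in POSITIVE_TOKENS:
        return 1
    if s in NEGATIVE_TOKENS:
        return 0
    raise ValueError(f"unknown class label {token!r}; expected one of "
                     f"{sorted(POSITIVE_TOKENS | NEGATIVE_TOKENS)}")


@dataclass
class ExpressionMatrix:
    """Two-class expression profile, samples as rows.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_probes)
        Continuous (log2-scale) expression values.
    sample_ids, probe_ids : lists of identifiers.
    labels : ndarray of shape (n_samples,)
        Binary class per sample, 1 = positive (tumor), 0 = negative.
    """

    values: np.ndarray
    sample_ids: list[str]
    probe_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D samples x probes matrix")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length does not match row count")
        if len(self.probe_ids) != p:
            raise ValueError("probe_ids length does not match column count")
        if self.labels.shape != (n,):
            raise ValueError("row count must equal label count")
        if len(set(self.probe_ids)) != p:
            raise ValueError("probe_ids must be unique")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both classes must be present")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_probes(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids,
                            columns=self.probe_ids)

    def subset_probes(self, probes: list[str]) -> "ExpressionMatrix":
        idx = [self.probe_ids.index(p) for p in probes]
        return ExpressionMatrix(self.values[:, idx], list(self.sample_ids),
                                list(probes), self.labels.copy())


@dataclass
class EdgeTable:
    """Undirected weighted edge list on a declared confidence scale.

    ``scale`` is ``"thousand"`` (scores in (0, 999], STRING style) or
    ``"unit"`` (scores in (0, 1]). Self-loops are removed; duplicate
    undirected pairs are collapsed keeping the maximum score.
    """

    edges: pd.DataFrame  # columns: node_a, node_b, score
    scale: str = "thousand"

    def __post_init__(self) -> None:
        if self.scale not in ("thousand", "unit"):
            raise ValueError(f"unknown score scale {self.scale!r}")
        df = self.edges.copy()
        df.columns = ["node_a", "node_b", "score"]
        df["node_a"] = df["node_a"].astype(str)
        df["node_b"] = df["node_b"].astype(str)
        df["score"] = df["score"].astype(float)
        hi = 999.0 if self.scale == "thousand" else 1.0
        bad = (df["score"] <= 0) | (df["score"] > hi)
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} scores outside the declared "
                f"{self.scale} scale (0, {hi}]")
        df = df[df["node_a"] != df["node_b"]]  # drop self-loops
        # canonical undirected order, collapse duplicates keeping max score
        a = df[["node_a", "node_b"]].min(axis=1)
        b = df[["node_a", "node_b"]].max(axis=1)
        df["node_a"], df["node_b"] = a, b
        df = (df.groupby(["node_a", "node_b"], as_index=False)["score"].max()
                .sort_values(["node_a", "node_b"], ignore_index=True))
        self.edges = df

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> list[str]:
        return sorted(set(self.edges["node_a"]) | set(self.edges["node_b"]))


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT semantics)."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sets = {name: set(members) for name, members in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)

    def universe(self) -> set[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return out


@dataclass
class IdMap:
    """Probe -> gene symbol -> protein id mapping (probe_id is the key)."""

    table: pd.DataFrame  # columns: probe_id, gene_symbol, protein_id

    def __post_init__(self) -> None:
        df = self.table.copy()
        for col in ("probe_id", "gene_symbol", "protein_id"):
            if col not in df.columns:
                df[col] = pd.NA
        df = df[["probe_id", "gene_symbol", "protein_id"]]
        df["probe_id"] = df["probe_id"].astype(str)
        if df["probe_id"].duplicated().any():
            raise ValueError("probe_id must be unique in an id map")
        self.table = df.reset_index(drop=True)

    def gene_for_probe(self, probe: str) -> str | None:
        hit = self.table.loc[self.table["probe_id"] == probe, "gene_symbol"]
        if hit.empty or pd.isna(hit.iloc[0]):
            return None
        return str(hit.iloc[0])

    def protein_for_gene(self, gene: str) -> str | None:
        hit = self.table.loc[self.table["gene_symbol"] == gene, "protein_id"]
        if hit.empty or pd.isna(hit.iloc[0]):
            return None
        return str(hit.iloc[0])


@dataclass
class RankedFeatureTable:
    """Probes ordered by a selection criterion.

    ``kind`` is one of ``"MaxRel"`` (mutual information with the class
    label, descending), ``"mRMR"`` (greedy relevance-minus-redundancy
    selection round), or ``"t-test"`` (two-sided Welch p ascending, score
    column holds the p-value).
    """

    table: pd.DataFrame  # columns: rank, probe_id, score
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in ("MaxRel", "mRMR", "t-test"):
            raise ValueError(f"unknown ranking kind {self.kind!r}")
        df = self.table.copy()
        df.columns = ["rank", "probe_id", "score"]
        df["rank"] = df["rank"].astype(int)
        df["probe_id"] = df["probe_id"].astype(str)
        df["score"] = df["score"].astype(float)
        expected = np.arange(1, len(df) + 1)
        if not np.array_equal(df["rank"].to_numpy(), expected):
            raise ValueError("ranks must be consecutive from 1")
        if self.kind == "MaxRel":
            s = df["score"].to_numpy()
            if np.any(np.diff(s) > 1e-12):
                raise ValueError("MaxRel scores must be non-increasing")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def top(self, k: int) -> list[str]:
        return self.table["probe_id"].head(k).tolist()


@dataclass
class IFSCurve:
    """Jackknife accuracy as a function of nested feature-set size."""

    table: pd.DataFrame  # columns: n_features, accuracy

    def __post_init__(self) -> None:
        df = self.table.copy()
        df.columns = ["n_features", "accuracy"]
        df["n_features"] = df["n_features"].astype(int)
        df["accuracy"] = df["accuracy"].astype(float)
        expected = np.arange(1, len(df) + 1)
        if not np.array_equal(df["n_features"].to_numpy(), expected):
            raise ValueError("feature counts must be consecutive from 1")
        acc = df["accuracy"].to_numpy()
        if np.any(acc < 0) or np.any(acc > 1):
            raise ValueError("accuracy must lie in [0, 1]")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def peak(self) -> tuple[int, float]:
        """Smallest feature count achieving the maximum accuracy."""
        acc = self.table["accuracy"].to_numpy()
        i = int(np.argmax(acc))  # first occurrence = smallest i
        return int(self.table["n_features"].iloc[i]), float(acc[i])


@dataclass
class PathRecord:
    """One seed-pair shortest path: node sequence and total cost."""

    source: str
    target: str
    nodes: list[str]
    cost: float
    reachable: bool = True

    def interior(self) -> list[str]:
        return self.nodes[1:-1] if self.reachable else []


@dataclass
class BetweennessTable:
    """Interior path genes with seed-pair betweenness and permutation p."""

    table: pd.DataFrame  # columns: gene, betweenness, p_value (may be NaN)

    def __post_init__(self) -> None:
        df = self.table.copy()
        if "p_value" not in df.columns:
            df["p_value"] = np.nan
        df = df[["gene", "betweenness", "p_value"]]
        df["gene"] = df["gene"].astype(str)
        df["betweenness"] = df["betweenness"].astype(int)
        if (df["betweenness"] <= 0).any():
            raise ValueError("betweenness counts must be positive")
        df = df.sort_values(["betweenness", "gene"],
                            ascending=[False, True], ignore_index=True)
        self.table = df

    def __len__(self) -> int:
        return len(self.table)
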