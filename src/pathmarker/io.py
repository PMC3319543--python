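"""Readers and writers for the delimited formats the pipeline consumes.

Expression matrices, STRING-style edge lists, GMT gene-set collections and
probe/gene/protein id maps are all plain delimited text. Readers validate
strictly and normalise to the canonical containers; every writer has a
matching reader that round-trips exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (BetweennessTable, EdgeTable, ExpressionMatrix,
                         GeneSetCollection, IdMap, IFSCurve,
                         RankedFeatureTable, parse_label)

logger = logging.getLogger(__name__)


def _read_delimited(path: str | Path, **kwargs) -> pd.DataFrame:
    path = Path(path)
    sep = kwargs.pop("sep", None)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    try:
        return pd.read_csv(path, sep=sep, **kwargs)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed delimited file {path}: {exc}") from exc


def read_expression_table(path: str | Path,
                          orientation: str = "samples-as-rows",
                          label_source: str | Path = "label",
                          sep: str | None = None,
                          impute_missing: bool = False) -> ExpressionMatrix:
    """Load a two-class expression matrix from a delimited file.

    Parameters
    ----------
    orientation : "samples-as-rows" or "probes-as-rows". The returned
        matrix is always samples-as-rows.
    label_source : name of an inline label column (samples-as-rows only),
        or a path to a two-column sample/label phenotype file. Label
        tokens: tumor/pos/positive/1/case vs normal/neg/negative/0/control.
    impute_missing : replace missing values by the per-probe median instead
        of rejecting the file.
    """
    if orientation not in ("samples-as-rows", "probes-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    if orientation == "samples-as-rows":
        # pandas mangles duplicate header names; check the raw header line
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        actual_sep = sep or ("\t" if Path(path).suffix.lower()
                             in (".tsv", ".txt") else ",")
        cols = header.split(actual_sep)[1:]
        if len(cols) != len(set(cols)):
            raise ValueError("duplicate probe ids in header; probe_ids "
                             "must be unique")
    df = _read_delimited(path, sep=sep, index_col=0)

    labels_inline = None
    if orientation == "samples-as-rows" and str(label_source) in df.columns:
        labels_inline = df[str(label_source)]
        df = df.drop(columns=[str(label_source)])

    if orientation == "probes-as-rows":
        df = df.T

    values = df.apply(pd.to_numeric, errors="raise")
    sample_ids = [str(s) for s in values.index]
    probe_ids = [str(p) for p in values.columns]

    if labels_inline is not None:
        labels = np.array([parse_label(v) for v in labels_inline])
    else:
        pheno_path = Path(label_source)
        if not pheno_path.exists():
            raise ValueError(
                f"label source {label_source!r} is neither a column of the "
                f"table nor an existing phenotype file")
        pheno = _read_delimited(pheno_path, header=None)
        pheno.columns = ["sample_id", "label"] + list(pheno.columns[2:])
        mapping = {str(r.sample_id): parse_label(r.label)
                   for r in pheno.itertuples()}
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"phenotype file lacks labels for {missing[:5]}")
        labels = np.array([mapping[s] for s in sample_ids])

    mat = values.to_numpy(dtype=float)
    if np.isnan(mat).any():
        if not impute_missing:
            raise ValueError(
                "expression matrix contains missing values "
                "(pass impute_missing=True for per-probe median imputation)")
        med = np.nanmedian(mat, axis=0)
        idx = np.where(np.isnan(mat))
        mat[idx] = med[idx[1]]

    return ExpressionMatrix(mat, sample_ids, probe_ids, labels)


def write_expression_table(em: ExpressionMatrix, path: str | Path,
                           label_column: str = "label") -> None:
    df = em.to_frame()
    df.insert(0, label_column,
              ["tumor" if y == 1 else "normal" for y in em.labels])
    sep = "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep)


def read_edge_table(path: str | Path, scale: str | None = None,
                    sep: str | None = r"\s+") -> EdgeTable:
    """Load a (node, node, score) edge list.

    ``scale`` is "thousand", "unit", or None to auto-detect (max score <= 1
    means unit scale). A header line is tolerated if its third field is not
    numeric. Self-loops are dropped with a warning; duplicate undirected
    pairs keep the maximum score.
    """
    df = _read_delimited(path, sep=sep, header=None, comment="#",
                         engine="python")
    if df.shape[1] < 3:
        raise ValueError(f"edge table {path} needs 3 columns, "
                         f"found {df.shape[1]}")
    df = df.iloc[:, :3]
    df.columns = ["node_a", "node_b", "score"]
    first = pd.to_numeric(df["score"].iloc[:1], errors="coerce")
    if first.isna().any():  # header row
        df = df.iloc[1:]
    df["score"] = pd.to_numeric(df["score"], errors="raise")
    if scale is None:
        scale = "unit" if df["score"].max() <= 1.0 else "thousand"
    loops = df["node_a"].astype(str) == df["node_b"].astype(str)
    if loops.any():
        logger.warning("dropping %d self-loop edge(s) in %s",
                       int(loops.sum()), path)
    return EdgeTable(df, scale=scale)


def write_edge_table(et: EdgeTable, path: str | Path) -> None:
    et.edges.to_csv(path, sep="\t", header=False, index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Load a GMT file: name TAB description TAB member TAB member..."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT lines need >= 3 tab-separated "
                    f"fields (name, description, members...)")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set {name!r}")
            sets[name] = {m for m in members if m}
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in gsc.names():
            desc = gsc.descriptions.get(name, "")
            members = "\t".join(sorted(gsc[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def read_id_map(path: str | Path, sep: str = "\t") -> IdMap:
    """Load a probe/gene/protein mapping table (header required)."""
    df = _read_delimited(path, sep=sep)
    rename = {}
    for col in df.columns:
        low = str(col).strip().lower().replace(" ", "_")
        if low in ("probe", "probe_id", "probe_name"):
            rename[col] = "probe_id"
        elif low in ("symbol", "gene", "gene_symbol"):
            rename[col] = "gene_symbol"
        elif low in ("protein", "protein_id"):
            rename[col] = "protein_id"
    df = df.rename(columns=rename)
    if "probe_id" not in df.columns:
        raise ValueError(f"id map {path} lacks a probe_id column")
    return IdMap(df)


def write_id_map(im: IdMap, path: str | Path) -> None:
    im.table.to_csv(path, sep="\t", index=False)


def map_probes_to_genes(probes: list[str], id_map: IdMap) -> list[str | None]:
    """Map probes to gene symbols, keeping probe order.

    Genes are deduplicated at gene level with the first occurrence kept;
    unmapped probes yield None entries with a warning.
    """
    lookup = dict(zip(id_map.table["probe_id"], id_map.table["gene_symbol"]))
    out: list[str | None] = []
    seen: set[str] = set()
    for probe in probes:
        gene = lookup.get(probe)
        if gene is None or pd.isna(gene):
            logger.warning("probe %s has no gene mapping", probe)
            out.append(None)
            continue
        gene = str(gene)
        if gene in seen:
            continue
        seen.add(gene)
        out.append(gene)
    return out


# ---------------------------------------------------------------------------
# result-table writers and round-trip readers

def write_ranked_table(rt: RankedFeatureTable, path: str | Path) -> None:
    df = rt.table.copy()
    df.insert(0, "kind", rt.kind)
    df.to_csv(path, sep="\t", index=False)


def read_ranked_table(path: str | Path) -> RankedFeatureTable:
    df = _read_delimited(path, sep="\t")
    kind = str(df["kind"].iloc[0])
    return RankedFeatureTable(df[["rank", "probe_id", "score"]], kind=kind)


def write_ifs_curve(curve: IFSCurve, path: str | Path) -> None:
    curve.table.to_csv(path, sep="\t", index=False)


def read_ifs_curve(path: str | Path) -> IFSCurve:
    return IFSCurve(_read_delimited(path, sep="\t"))


def write_betweenness_table(bt: BetweennessTable, path: str | Path) -> None:
    bt.table.to_csv(path, sep="\t", index=False)


def read_betweenness_table(path: str | Path) -> BetweennessTable:
    return BetweennessTable(_read_delimited(path, sep="\t"))


def write_tables(results: dict[str, object], out_dir: str | Path) -> list[Path]:
    """Write a named bundle of result objects as TSVs under ``out_dir``.

    Dispatches on type; plain DataFrames are written as-is. Returns the
    written paths in deterministic (name-sorted) order.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(results):
        obj = results[name]
        path = out_dir / f"{name}.tsv"
        if isinstance(obj, RankedFeatureTable):
            write_ranked_table(obj, path)
        elif isinstance(obj, IFSCurve):
            write_ifs_curve(obj, path)
        elif isinstance(obj, BetweennessTable):
            write_betweenness_table(obj, path)
        elif isinstance(obj, EdgeTable):
            write_edge_table(obj, path)
        elif isinstance(obj, pd.DataFrame):
            obj.to_csv(path, sep="\t", index=False)
        else:
            raise TypeError(f"no writer for result type {type(obj).__name__}")
        written.append(path)
    return written
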