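"""Readers and writers for the interchange formats, plus packaged fixtures.

All tables are tab-separated with ``#`` comment headers; floats are written
with 17 significant digits so a write -> read round trip reproduces values
exactly.  Malformed inputs raise with the offending line number.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .de import AnnotationTable, ExpressionMatrix, TREATMENTS
from .network import RegulatoryNetwork, SignedEdge

FLOAT_FMT = "%.17g"
FIXTURE_NAMES = ("table1", "table2", "table3", "curated_tf_list")


class FormatError(ValueError):
    """Malformed input file (message carries the line number)."""


def _data_lines(path: str | Path) -> list[tuple[int, str]]:
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            out.append((lineno, line))
    if not out:
        raise FormatError(f"{path}: no data lines")
    return out


# ---------------------------------------------------------------------------
# expression / design / annotation
# ---------------------------------------------------------------------------

def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# log2 expression matrix (genes x samples)\n")
        fh.write("gene_id\t" + "\t".join(expr.sample_ids) + "\n")
        for gid, row in zip(expr.gene_ids, expr.values):
            fh.write(gid + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_expression(path: str | Path, design: pd.DataFrame) -> ExpressionMatrix:
    """Read a tab-separated expression matrix; ``design`` supplies metadata."""
    lines = _data_lines(path)
    lineno, header = lines[0]
    cols = header.split("\t")
    if len(cols) < 2 or cols[0] != "gene_id":
        raise FormatError(f"{path}:{lineno}: header must start with 'gene_id'")
    sample_ids = cols[1:]
    if len(set(sample_ids)) != len(sample_ids):
        raise FormatError(f"{path}:{lineno}: duplicate sample ids in header")
    gene_ids: list[str] = []
    seen: set[str] = set()
    rows = []
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise FormatError(
                f"{path}:{lineno}: expected {len(cols)} fields, got {len(parts)}")
        if parts[0] in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {parts[0]!r}")
        seen.add(parts[0])
        gene_ids.append(parts[0])
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric value ({exc})") from None
    design = design.loc[sample_ids]
    return ExpressionMatrix(gene_ids=gene_ids, sample_ids=sample_ids,
                            values=np.array(rows), design=design)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tecotype\ttreatment\treplicate\n")
        for sid, row in design.iterrows():
            fh.write(f"{sid}\t{row['ecotype']}\t{row['treatment']}\t{row['replicate']}\n")


def read_design(path: str | Path) -> pd.DataFrame:
    """Design table: sample_id, ecotype, treatment, replicate (tab or comma)."""
    lines = _data_lines(path)
    lineno, header = lines[0]
    sep = "\t" if "\t" in header else ","
    cols = header.split(sep)
    required = ["sample_id", "ecotype", "treatment", "replicate"]
    if cols[:4] != required:
        raise FormatError(f"{path}:{lineno}: header must be {required}")
    recs = []
    seen: set[str] = set()
    for lineno, line in lines[1:]:
        parts = line.split(sep)
        if len(parts) != len(cols):
            raise FormatError(f"{path}:{lineno}: ragged row")
        if parts[0] in seen:
            raise FormatError(f"{path}:{lineno}: duplicate sample id {parts[0]!r}")
        seen.add(parts[0])
        if parts[2] not in TREATMENTS:
            raise FormatError(
                f"{path}:{lineno}: unknown treatment label {parts[2]!r}")
        try:
            rep = int(parts[3])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: replicate must be an integer") from None
        recs.append((parts[0], parts[1], parts[2], rep))
    df = pd.DataFrame(recs, columns=required).set_index("sample_id")
    return df


def write_annotation(annot: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttags\tfamily\n")
        for gid in sorted(annot.tags):
            fh.write(f"{gid}\t{';'.join(sorted(annot.tags[gid]))}\t"
                     f"{annot.family.get(gid, '')}\n")


def read_annotation(path: str | Path) -> AnnotationTable:
    lines = _data_lines(path)
    lineno, header = lines[0]
    if header.split("\t")[:2] != ["gene_id", "tags"]:
        raise FormatError(f"{path}:{lineno}: header must start 'gene_id\\ttags'")
    tags: dict[str, frozenset[str]] = {}
    family: dict[str, str] = {}
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: ragged row")
        gid = parts[0]
        if gid in tags:
            raise FormatError(f"{path}:{lineno}: duplicate gene id {gid!r}")
        tags[gid] = frozenset(t for t in parts[1].split(";") if t)
        if len(parts) > 2 and parts[2]:
            family[gid] = parts[2]
    return AnnotationTable(tags=tags, family=family)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

def write_edge_list(net: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# signed bipartite TF->target network\n")
        fh.write("tf_id\ttarget_id\tr\tsign\n")
        for e in net.edges:
            fh.write(f"{e.tf_id}\t{e.target_id}\t{FLOAT_FMT % e.weight}\t{e.sign}\n")


def write_sif(net: RegulatoryNetwork, path: str | Path) -> None:
    """SIF-like export: 'tf activates|represses target' per line."""
    with open(path, "w") as fh:
        for e in net.edges:
            rel = "activates" if e.sign > 0 else "represses"
            fh.write(f"{e.tf_id}\t{rel}\t{e.target_id}\n")


def read_edge_list(path: str | Path) -> RegulatoryNetwork:
    lines = _data_lines(path)
    lineno, header = lines[0]
    if header.split("\t") != ["tf_id", "target_id", "r", "sign"]:
        raise FormatError(f"{path}:{lineno}: bad edge-list header")
    edges = []
    tfs: list[str] = []
    targets: list[str] = []
    for lineno, line in lines[1:]:
        parts = line.split("\t")
        if len(parts) != 4:
            raise FormatError(f"{path}:{lineno}: ragged row")
        tf, tg = parts[0], parts[1]
        try:
            r = float(parts[2])
            sign = int(parts[3])
        except ValueError:
            raise FormatError(f"{path}:{lineno}: non-numeric r/sign") from None
        expected = 1 if r > 0 else -1
        if sign != expected:
            raise FormatError(
                f"{path}:{lineno}: sign {sign} inconsistent with r = {r}")
        try:
            edges.append(SignedEdge(tf, tg, r, sign))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        if tf not in tfs:
            tfs.append(tf)
        if tg not in targets:
            targets.append(tg)
    return RegulatoryNetwork(tfs=tfs, targets=targets, edges=edges)


# ---------------------------------------------------------------------------
# generic tables, matrices, gene sets
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path: str | Path, comment: str = "") -> None:
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip")


def write_matrix(values: np.ndarray, row_ids: list[str], col_ids: list[str],
                 path: str | Path, comment: str = "") -> None:
    df = pd.DataFrame(values, index=row_ids, columns=col_ids)
    with open(path, "w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index_label="id", float_format=FLOAT_FMT)


def read_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0,
                       float_precision="round_trip")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Gene sets from two-column (set_id TAB gene_id) or GMT format."""
    lines = _data_lines(path)
    sets: dict[str, set[str]] = {}
    # GMT rows have >= 3 fields with a description in the second column
    is_gmt = all(len(line.split("\t")) >= 3 for _, line in lines)
    header_skipped = False
    for lineno, line in lines:
        parts = line.split("\t")
        if is_gmt:
            sets.setdefault(parts[0], set()).update(p for p in parts[2:] if p)
        else:
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns")
            if not header_skipped and parts == ["set_id", "gene_id"]:
                header_skipped = True
                continue
            sets.setdefault(parts[0], set()).add(parts[1])
    return sets


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged study table by name.

    ``table1`` — per-ecotype differential-expression counts (10 rows);
    ``table2`` — per-TF network degree table (35 rows; the printed
    activation/repression column labels disagree with the text, preserved
    verbatim — see the file's header comment);
    ``table3`` — per-TF responsive-ecotype calls (35 rows, format fixture);
    ``curated_tf_list`` — the 35 printed members of the curated
    heat-responsive TF list.
    """
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")
    ref = resources.files("heatnca") / "fixtures" / f"{name}.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
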