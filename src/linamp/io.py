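"""Readers and writers for the package's exchange formats.

Count matrices travel as Matrix-Market coordinate files with barcodes and
features sidecar tables (genes as rows, the droplet convention); read
sets as plain TSV (optionally gzipped) with one row per read; panels as a
fixed-schema CSV; transcripts as FASTA.  Every writer/reader pair
round-trips exactly: integer counts bit-exact, identifiers byte-exact.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.io import mmread, mmwrite

from .ampsim import ReadSet
from .errors import ParseError
from .paneldesign import GenePanel

__all__ = [
    "umi_to_seq",
    "seq_to_umi",
    "write_counts_mtx",
    "read_counts_mtx",
    "write_reads",
    "read_reads",
    "write_panel_csv",
    "read_panel_csv",
    "read_fasta",
    "write_fasta",
    "write_ground_truth",
]

_BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(_BASES)}


def umi_to_seq(code: int, umi_length: int) -> str:
    """Decode an integer UMI code to its base-4 nucleotide string."""
    out = []
    x = int(code)
    for _ in range(umi_length):
        out.append(_BASES[x % 4])
        x //= 4
    return "".join(reversed(out))


def seq_to_umi(seq: str) -> int:
    code = 0
    for b in seq:
        if b not in _BASE_CODE:
            raise ParseError(f"invalid base {b!r} in UMI {seq!r}")
        code = code * 4 + _BASE_CODE[b]
    return code


def _decode_umis(codes: np.ndarray, umi_length: int) -> np.ndarray:
    """Vectorised base-4 decode of UMI codes to fixed-length ACGT strings."""
    powers = 4 ** np.arange(umi_length - 1, -1, -1, dtype=np.int64)
    digits = (codes[:, None] // powers) % 4
    chars = np.frombuffer(b"ACGT", dtype="S1")[digits]
    return chars.view(f"S{umi_length}").ravel().astype(str)


def _check_unique(ids, what: str) -> None:
    s = pd.Index(ids)
    if s.has_duplicates:
        dup = s[s.duplicated()][0]
        raise ParseError(f"duplicate {what} identifier: {dup!r}")


def write_counts_mtx(adata: ad.AnnData, outdir) -> None:
    """Write matrix.mtx (genes x cells, 1-based coordinates) + barcodes.tsv +
    features.tsv."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    mmwrite(
        str(outdir / "matrix.mtx"),
        X.T.tocoo().astype(np.int64),
        field="integer",
        comment="genes as rows, cells as columns; coordinates are 1-based",
    )
    (outdir / "barcodes.tsv").write_text("".join(f"{b}\n" for b in adata.obs_names))
    (outdir / "features.tsv").write_text("".join(f"{g}\n" for g in adata.var_names))


def read_counts_mtx(indir) -> ad.AnnData:
    indir = Path(indir)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (indir / name).exists():
            raise ParseError(f"missing {name} in {indir}")
    try:
        mat = mmread(str(indir / "matrix.mtx"))
    except Exception as exc:  # scipy raises bare ValueError on malformed headers
        raise ParseError(f"malformed matrix.mtx: {exc}") from exc
    barcodes = (indir / "barcodes.tsv").read_text().splitlines()
    features = (indir / "features.tsv").read_text().splitlines()
    _check_unique(barcodes, "barcode")
    _check_unique(features, "feature")
    if mat.shape != (len(features), len(barcodes)):
        raise ParseError(
            f"matrix shape {mat.shape} does not match {len(features)} features x "
            f"{len(barcodes)} barcodes"
        )
    X = sp.csr_matrix(mat.T).astype(np.int64)
    return ad.AnnData(
        X=X,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_barcode")),
        var=pd.DataFrame(index=pd.Index(features, name="gene_id")),
    )


def _open_text(path, mode: str):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode + "t")
    return open(path, mode)


def write_reads(reads: ReadSet, path) -> None:
    """One row per read (cell_barcode, umi, gene), tab-separated, with header
    comments carrying the metadata needed for an exact round-trip.

    ``.gz`` paths are compressed transparently.  Row order is the read set's
    deterministic generation order.
    """
    with _open_text(path, "w") as fh:
        fh.write(f"#umi_length={reads.umi_length}\n")
        fh.write(f"#read_budget={reads.read_budget}\n")
        fh.write("#barcodes=" + ",".join(map(str, reads.cell_ids)) + "\n")
        fh.write("#genes=" + ",".join(map(str, reads.gene_ids)) + "\n")
        fh.write("#underfilled=" + ",".join(map(str, reads.underfilled_cells.tolist())) + "\n")
        fh.write("cell_barcode\tumi\tgene\n")
        if reads.n_reads:
            df = pd.DataFrame(
                {
                    "cell_barcode": np.asarray(reads.cell_ids)[reads.cell],
                    "umi": _decode_umis(reads.umi, reads.umi_length),
                    "gene": np.asarray(reads.gene_ids)[reads.gene],
                }
            )
            df.to_csv(fh, sep="\t", index=False, header=False)


def read_reads(path) -> ReadSet:
    meta: dict[str, str] = {}
    with _open_text(path, "r") as fh:
        lineno = 0
        for line in fh:
            lineno += 1
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].partition("=")
                meta[key] = val
                continue
            if line != "cell_barcode\tumi\tgene":
                raise ParseError(f"line {lineno}: unexpected header {line!r}")
            break
        else:
            raise ParseError("read table has no header row")
        for key in ("umi_length", "barcodes", "genes"):
            if key not in meta:
                raise ParseError(f"missing #{key}= metadata header")
        df = pd.read_csv(
            fh, sep="\t", header=None, names=["cell_barcode", "umi", "gene"], dtype=str
        )
    first_data_line = lineno + 1

    def _bad_line(mask: np.ndarray) -> int:
        return first_data_line + int(np.nonzero(mask)[0][0])

    if df.isna().any(axis=None):
        raise ParseError(
            f"line {_bad_line(df.isna().any(axis=1).to_numpy())}: "
            "expected 3 tab-separated fields"
        )
    umi_length = int(meta["umi_length"])
    cell_ids = meta["barcodes"].split(",")
    gene_ids = meta["genes"].split(",")
    cell_rows = pd.Index(cell_ids).get_indexer(df["cell_barcode"])
    if (cell_rows < 0).any():
        bad = _bad_line(cell_rows < 0)
        raise ParseError(f"line {bad}: unknown cell barcode {df['cell_barcode'].iloc[bad - first_data_line]!r}")
    gene_rows = pd.Index(gene_ids).get_indexer(df["gene"])
    if (gene_rows < 0).any():
        bad = _bad_line(gene_rows < 0)
        raise ParseError(f"line {bad}: unknown gene {df['gene'].iloc[bad - first_data_line]!r}")
    valid_umi = df["umi"].str.fullmatch(f"[ACGT]{{{umi_length}}}").to_numpy()
    if not valid_umi.all():
        bad = _bad_line(~valid_umi)
        raise ParseError(f"line {bad}: invalid UMI {df['umi'].iloc[bad - first_data_line]!r}")
    if len(df):
        chars = df["umi"].to_numpy().astype(f"S{umi_length}").view("S1").reshape(len(df), umi_length)
        digits = np.searchsorted(np.frombuffer(b"ACGT", dtype="S1"), chars)
        powers = 4 ** np.arange(umi_length - 1, -1, -1, dtype=np.int64)
        umi_rows = (digits * powers).sum(axis=1)
    else:
        umi_rows = np.array([], dtype=np.int64)
    under = meta.get("underfilled", "")
    return ReadSet(
        cell=np.asarray(cell_rows, dtype=np.int64),
        gene=np.asarray(gene_rows, dtype=np.int64),
        umi=np.asarray(umi_rows, dtype=np.int64),
        cell_ids=np.array(cell_ids),
        gene_ids=np.array(gene_ids),
        umi_length=umi_length,
        read_budget=int(meta.get("read_budget", "0") or 0),
        underfilled_cells=np.array(
            [int(x) for x in under.split(",") if x != ""], dtype=np.int64
        ),
    )


_PANEL_COLUMNS = ["gene_id", "specific_seq", "handle_seq", "target_position", "is_negative_control"]


def write_panel_csv(panel: GenePanel, path) -> None:
    """Fixed-schema panel CSV: gene_id, specific_seq, handle_seq,
    target_position, is_negative_control (true/false), one header row."""
    df = panel.to_dataframe()
    df["is_negative_control"] = np.where(df["is_negative_control"], "true", "false")
    df.to_csv(path, index=False, columns=_PANEL_COLUMNS)


def read_panel_csv(path) -> GenePanel:
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:
        raise ParseError(f"cannot parse panel CSV: {exc}") from exc
    if list(df.columns) != _PANEL_COLUMNS:
        raise ParseError(f"panel CSV columns must be {_PANEL_COLUMNS}, got {list(df.columns)}")
    _check_unique(df["gene_id"], "gene")
    flags = df["is_negative_control"].str.lower()
    bad = ~flags.isin(["true", "false"])
    if bad.any():
        raise ParseError(
            f"is_negative_control must be true/false; offending gene "
            f"{df.loc[bad, 'gene_id'].iloc[0]!r}"
        )
    df = df.assign(
        target_position=df["target_position"].astype(int),
        is_negative_control=(flags == "true"),
    )
    return GenePanel.from_dataframe(df)


def read_fasta(path) -> dict[str, str]:
    """Transcript sequences (mRNA sense, 5'->3') keyed by record id."""
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise ParseError(f"duplicate FASTA identifier: {rec.id!r}")
        out[rec.id] = str(rec.seq).upper()
    if not out:
        raise ParseError(f"no FASTA records found in {path}")
    return out


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def write_ground_truth(cells, model, outdir) -> None:
    """Tidy nonzero molecule table plus a gene metadata table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cells.to_long().to_csv(outdir / "ground_truth_counts.csv", index=False)
    meta = model.genes.copy()
    for cond in model.conditions:
        meta[f"multiplier_{cond}"] = model.multipliers[cond]
    meta.to_csv(outdir / "gene_metadata.csv")
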