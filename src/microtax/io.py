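"""Format readers/writers and the versioned model archive.

FASTA reading accepts wrapped and unwrapped dialects; record IDs are the
first whitespace-delimited token after '>'.  Writing is unwrapped, so a
write/read cycle is byte-stable.  Taxonomy tables are TSV with a header
(sequence_id, genus, optional extra lineage columns).  Result tables are
TSV with the fixed column order

    query_id  taxon  d_score  r_score  r_probability  flags

missing values written as "NA" and run provenance echoed in leading '#'
comment lines.

The model archive is a zip of .npy members plus a JSON manifest, written
with fixed timestamps so identical models serialize to identical bytes.
"""

from __future__ import annotations

import io as _io
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser

FORMAT_VERSION = "microtax-model-1"

RESULT_COLUMNS = ("query_id", "taxon", "d_score", "r_score", "r_probability", "flags")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a multi-FASTA file into (id, sequence) pairs.

    IDs are the first whitespace token of the header.  Duplicate IDs and
    empty files are errors.
    """
    path = Path(path)
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise ValueError(f"{path}: empty FASTA file")
        if first != ">":
            raise ValueError(f"{path}: line 1: expected '>' header")
        fh.seek(0)
        for title, seq in SimpleFastaParser(fh):
            rid = title.split()[0] if title.split() else ""
            if not rid:
                raise ValueError(f"{path}: record with empty ID")
            if rid in seen:
                raise ValueError(f"{path}: duplicate sequence ID {rid!r}")
            seen.add(rid)
            records.append((rid, seq))
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    """Write (id, sequence) pairs as unwrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n{seq}\n")


def read_taxonomy(path) -> pd.DataFrame:
    """Read a TSV taxonomy table with at least sequence_id and genus columns."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    for col in ("sequence_id", "genus"):
        if col not in df.columns:
            raise ValueError(f"taxonomy table lacks required column {col!r}")
    if df["sequence_id"].duplicated().any():
        dup = df["sequence_id"][df["sequence_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sequence_id in taxonomy table: {dup!r}")
    if (df["genus"].isna() | (df["genus"].str.strip() == "")).any():
        raise ValueError("taxonomy table contains empty genus names")
    if df["genus"].str.contains("\t").any():
        raise ValueError("genus names must not contain tabs")
    return df


def write_taxonomy(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def taxonomy_map(records: list[tuple[str, str]], taxonomy: pd.DataFrame) -> dict[str, str]:
    """Map record IDs to genus labels, erroring on missing IDs (up to 10 listed)."""
    table = dict(zip(taxonomy["sequence_id"], taxonomy["genus"]))
    missing = [rid for rid, _ in records if rid not in table]
    if missing:
        shown = ", ".join(missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(f"sequence IDs missing from taxonomy table: {shown}{more}")
    return {rid: table[rid] for rid, _ in records}


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        if not np.isfinite(value):
            return "NA"
        return f"{value:.6g}"
    return str(value)


def write_results(records, path, comments: list[str] | None = None) -> None:
    """Write ClassificationRecords as TSV; NA for missing, '#' provenance lines."""
    with open(path, "w") as fh:
        for line in comments or []:
            fh.write(f"# {line}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for rec in records:
            flags = ",".join(rec.flags) if rec.flags else ""
            row = [
                rec.query_id,
                rec.taxon if rec.taxon is not None else "NA",
                _fmt(rec.d_score),
                _fmt(rec.r_score),
                _fmt(rec.r_probability),
                flags,
            ]
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# model archive

_EPOCH = (1980, 1, 1, 0, 0, 0)  # fixed zip timestamp => byte-stable archives


def _np_bytes(arr: np.ndarray) -> bytes:
    buf = _io.BytesIO()
    np.save(buf, arr, allow_pickle=False)
    return buf.getvalue()


def _write_member(zf: zipfile.ZipFile, name: str, data: bytes) -> None:
    info = zipfile.ZipInfo(name, date_time=_EPOCH)
    info.compress_type = zipfile.ZIP_DEFLATED
    zf.writestr(info, data)


def save_model(model, path) -> None:
    """Serialize a TaxMachineModel to a deterministic zip archive."""
    lp, norm, stats = model.logprob, model.norm, model.stats
    manifest = {
        "format_version": FORMAT_VERSION,
        "k": lp.k,
        "pseudo_count": lp.pseudo_count,
        "log_base": lp.log_base,
        "mean_coef": list(norm.mean_coef),
        "sd_coef": list(norm.sd_coef),
        "fit_range": list(norm.fit_range),
        "metadata": model.metadata,
    }
    with zipfile.ZipFile(path, "w") as zf:
        _write_member(zf, "manifest.json", json.dumps(manifest, sort_keys=True).encode())
        _write_member(zf, "Q.npy", _np_bytes(lp.Q))
        _write_member(zf, "taxa.npy", _np_bytes(np.asarray(lp.taxa)))
        _write_member(zf, "stats_genera.npy", _np_bytes(np.asarray(stats.genera)))
        for name in ("sizes", "mean", "raw_sd", "size_sd", "shrunk_sd", "ecdf"):
            _write_member(zf, f"stats_{name}.npy", _np_bytes(getattr(stats, name)))


def load_model(path):
    """Load a model archive written by :func:`save_model`."""
    from .multinomial import LogProbMatrix
    from .taxmachine import TaxMachineModel
    from .uncertainty import GenusScoreStats, LengthNormModel

    def _read(zf, name):
        return np.load(_io.BytesIO(zf.read(name)), allow_pickle=False)

    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("format_version") != FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format {manifest.get('format_version')!r}"
            )
        lp = LogProbMatrix(
            Q=_read(zf, "Q.npy"),
            taxa=[str(t) for t in _read(zf, "taxa.npy")],
            k=int(manifest["k"]),
            pseudo_count=float(manifest["pseudo_count"]),
            log_base=int(manifest["log_base"]),
        )
        norm = LengthNormModel(
            mean_coef=tuple(manifest["mean_coef"]),
            sd_coef=tuple(manifest["sd_coef"]),
            fit_range=tuple(manifest["fit_range"]),
        )
        stats = GenusScoreStats(
            genera=[str(g) for g in _read(zf, "stats_genera.npy")],
            sizes=_read(zf, "stats_sizes.npy"),
            mean=_read(zf, "stats_mean.npy"),
            raw_sd=_read(zf, "stats_raw_sd.npy"),
            size_sd=_read(zf, "stats_size_sd.npy"),
            shrunk_sd=_read(zf, "stats_shrunk_sd.npy"),
            ecdf=_read(zf, "stats_ecdf.npy"),
        )
    return TaxMachineModel(logprob=lp, norm=norm, stats=stats,
                           metadata=manifest["metadata"])
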