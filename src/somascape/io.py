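"""Strict text I/O for the pipeline's on-disk formats.

All tabular files are tab-separated UTF-8 with '#'-prefixed header/metadata
lines and no quoting.  Writers stamp a metadata line carrying the package
version, the seed in force and (for channel-indexed tables) the 96-channel
order, so every file is self-describing.  Readers are strict: malformed lines,
coordinate violations and non-ACGT alleles raise errors naming the line number.
Internally coordinates are 0-based half-open; emitted VCF positions are
1-based, as are the site-count tables (which carry pileup positions).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import channels as ch


class FormatError(ValueError):
    """A parse failure, pointing at the offending file line."""

    def __init__(self, path, line_no: int, message: str) -> None:
        super().__init__(f"{path}:{line_no}: {message}")
        self.path = str(path)
        self.line_no = line_no


def _metadata_lines(seed: int | None = None, channel_order: bool = False, **extra) -> list[str]:
    meta = {"somascape": __version__}
    if seed is not None:
        meta["seed"] = seed
    meta.update(extra)
    lines = ["# " + " ".join(f"{k}={v}" for k, v in meta.items())]
    if channel_order:
        lines.append("# channel_order=" + ",".join(ch.CHANNELS_96))
    return lines


def write_tsv(
    df: pd.DataFrame,
    path,
    seed: int | None = None,
    channel_order: bool = False,
    index: bool = False,
    **extra,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for line in _metadata_lines(seed, channel_order, **extra):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.6g", lineterminator="\n")


def read_tsv(path, required: tuple[str, ...] = (), index_col=None) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(path, 1, f"missing required columns {missing}")
    return df


# -- SiteCounts ------------------------------------------------------------

SITE_COLUMNS = (
    "chrom", "pos", "ref", "alt", "t_ref", "t_alt", "n_ref", "n_alt",
    "context", "gene", "effect", "mapq_pass_fraction", "mismatch_pass_fraction",
)


def write_site_counts(df: pd.DataFrame, path, seed: int | None = None) -> None:
    write_tsv(df[list(SITE_COLUMNS)], path, seed=seed)


def read_site_counts(path) -> pd.DataFrame:
    df = read_tsv(path, required=SITE_COLUMNS)
    df["gene"] = df["gene"].fillna("")
    _validate_sites(df, path)
    return df


def _validate_sites(df: pd.DataFrame, path) -> None:
    header_offset = 3  # metadata line + header line + 1-based data start
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + header_offset
        if row.pos < 1:
            raise FormatError(path, line, f"position {row.pos} < 1")
        for col in ("t_ref", "t_alt", "n_ref", "n_alt"):
            if getattr(row, col) < 0:
                raise FormatError(path, line, f"negative count in {col}")
        alleles = str(row.ref) + str(row.alt)
        if any(b not in "ACGTN-" for b in alleles):
            raise FormatError(path, line, f"non-ACGT allele {row.ref}>{row.alt}")


# -- depth bins ------------------------------------------------------------

DEPTH_COLUMNS = ("chrom", "bin_start", "t_depth", "n_depth")


def write_depth_bins(df: pd.DataFrame, path, seed: int | None = None) -> None:
    write_tsv(df[list(DEPTH_COLUMNS)], path, seed=seed)


def read_depth_bins(path) -> pd.DataFrame:
    return read_tsv(path, required=DEPTH_COLUMNS)


# -- SEG -------------------------------------------------------------------

SEG_COLUMNS = ("sample", "chrom", "start", "end", "n_bins", "mean_log2", "state")


def write_seg(df: pd.DataFrame, path, seed: int | None = None) -> None:
    out = df.copy()
    if "sample" not in out.columns:
        out.insert(0, "sample", "NA")
    if "state" not in out.columns:
        out["state"] = "NA"
    write_tsv(out[list(SEG_COLUMNS)], path, seed=seed)


def read_seg(path) -> pd.DataFrame:
    """Strict line-by-line SEG parser with line-numbered errors."""
    path = Path(path)
    rows = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if header is None:
                header = parts
                missing = [c for c in SEG_COLUMNS if c not in header]
                if missing:
                    raise FormatError(path, line_no, f"missing SEG columns {missing}")
                continue
            if len(parts) != len(header):
                raise FormatError(
                    path, line_no,
                    f"expected {len(header)} fields, found {len(parts)}",
                )
            rec = dict(zip(header, parts))
            try:
                rec["start"] = int(rec["start"])
                rec["end"] = int(rec["end"])
                rec["n_bins"] = int(rec["n_bins"])
                rec["mean_log2"] = float(rec["mean_log2"])
            except ValueError as exc:
                raise FormatError(path, line_no, f"unparseable numeric field: {exc}") from None
            if rec["end"] <= rec["start"]:
                raise FormatError(path, line_no, f"end {rec['end']} <= start {rec['start']}")
            rows.append(rec)
    if header is None:
        raise FormatError(path, 1, "empty SEG file")
    return pd.DataFrame(rows, columns=list(SEG_COLUMNS))


# -- BED -------------------------------------------------------------------

def write_bed(df: pd.DataFrame, path, name_col: str = "state") -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for row in df.itertuples(index=False):
            name = getattr(row, name_col, ".")
            fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{name}\n")


# -- variant blacklists / whitelists --------------------------------------

def read_variant_list(path) -> set[tuple[str, int, str, str]]:
    """dbSNP-/COSMIC-like flat list: chrom, pos, ref, alt per line."""
    path = Path(path)
    out = set()
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(path, line_no, "expected chrom, pos, ref, alt")
            try:
                pos = int(parts[1])
            except ValueError:
                raise FormatError(path, line_no, f"bad position {parts[1]!r}") from None
            out.add((parts[0], pos, parts[2], parts[3]))
    return out


def write_variant_list(variants, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, pos, ref, alt in sorted(variants):
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")


# -- GMT -------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    path = Path(path)
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(path, line_no, "GMT lines need name, description, >= 1 gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# -- VCF -------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
##source=somascape {version}
##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic candidate">
##INFO=<ID=VAF,Number=1,Type=Float,Description="Tumor variant allele fraction">
##INFO=<ID=FP,Number=1,Type=Float,Description="Fisher exact p-value (one-sided)">
##FILTER=<ID=low_mapq_evidence,Description="Too few reads surviving mapping-quality filter">
##FILTER=<ID=high_mismatch_evidence,Description="Too few reads surviving mismatch filter">
##FILTER=<ID=known_snp,Description="Registered in a germline variant list">
##FILTER=<ID=synonymous,Description="Synonymous change">
##FILTER=<ID=germline_band,Description="Copy-neutral VAF in the germline band">
##FILTER=<ID=low_support,Description="Insufficient statistical or read support">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(calls: pd.DataFrame, path, seed: int | None = None) -> None:
    """VCF v4.2; FILTER carries the accumulated filter flags (PASS if none)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_VCF_HEADER.format(version=__version__))
        ordered = calls.sort_values(["chrom", "pos"], kind="mergesort")
        for row in ordered.itertuples(index=False):
            filt = row.filter_flags if row.filter_flags else "PASS"
            p = getattr(row, "p_value", np.nan)
            info = f"SOMATIC;VAF={row.vaf:.4g}"
            if np.isfinite(p):
                info += f";FP={p:.4g}"
            fh.write(
                f"{row.chrom}\t{row.pos}\t.\t{row.ref}\t{row.alt}\t.\t{filt}\t{info}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    """Minimal strict reader of the VCFs this package writes."""
    path = Path(path)
    rows = []
    saw_header = False
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise FormatError(path, line_no, f"expected 8 VCF columns, found {len(parts)}")
            chrom, pos, _, ref, alt, _, filt, info = parts
            try:
                pos = int(pos)
            except ValueError:
                raise FormatError(path, line_no, f"bad POS {parts[1]!r}") from None
            if pos < 1:
                raise FormatError(path, line_no, "POS must be >= 1")
            if any(b not in "ACGTN" for b in ref + alt):
                raise FormatError(path, line_no, f"non-ACGT allele {ref}>{alt}")
            fields = dict(
                f.split("=", 1) for f in info.split(";") if "=" in f
            )
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": ref,
                    "alt": alt,
                    "filter_flags": "" if filt == "PASS" else filt,
                    "status": "accepted" if filt == "PASS" else "rejected",
                    "vaf": float(fields.get("VAF", "nan")),
                    "p_value": float(fields.get("FP", "nan")),
                }
            )
    if not saw_header:
        raise FormatError(path, 1, "missing #CHROM header line")
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "filter_flags", "status", "vaf", "p_value"]
    )


# -- MAF-like --------------------------------------------------------------

MAF_COLUMNS = (
    "sample", "gene", "chrom", "pos", "ref", "alt", "effect", "context",
    "vaf", "p_value", "status", "filter_flags",
)


def write_maf(calls: pd.DataFrame, path, seed: int | None = None) -> None:
    out = calls.copy()
    if "sample" not in out.columns:
        out.insert(0, "sample", "NA")
    write_tsv(out[[c for c in MAF_COLUMNS if c in out.columns]], path, seed=seed)


# -- truth JSON ------------------------------------------------------------

def write_truth(truth, path, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "somascape": __version__,
        "seed": seed,
        "somatic": truth.somatic.to_dict(orient="records"),
        "germline": truth.germline.to_dict(orient="records"),
        "cna_segments": truth.cna_segments.to_dict(orient="records"),
        "exposures": truth.exposures.to_dict(orient="records"),
        "region_assignment": (
            truth.region_assignment.to_dict(orient="records")
            if truth.region_assignment is not None
            else None
        ),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def read_truth(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


# -- FASTA (small, for I/O testing of context handling) --------------------

def write_fasta(seqs: dict[str, str], path, width: int = 60) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    path = Path(path)
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path, encoding="utf-8") as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise FormatError(path, line_no, f"duplicate sequence {name}")
                seqs[name] = []
            else:
                if name is None:
                    raise FormatError(path, line_no, "sequence data before a header")
                seqs[name].append(line.upper())
    return {k: "".join(v) for k, v in seqs.items()}
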