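"""Readers and writers for the external file formats.

Supported formats: MAF-like somatic SNV tables, minimal VCF, COSMIC-v2
signature catalogs, STRING-like PPI edge lists, exposure tables, and
JSON-serialized classifier models.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import SignatureCatalog
from .network import PPINetwork, normalize_symbol
from .records import MutationRecord
from .spectrum import CHANNELS, Spectrum96

logger = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class FormatError(ValueError):
    """A file does not conform to its expected layout."""


# ---------------------------------------------------------------------------
# MAF / VCF

_MAF_REQUIRED = [
    "Tumor_Sample_Barcode",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
]


def _norm_chrom(chrom: str) -> str:
    chrom = str(chrom)
    return chrom[3:] if chrom.lower().startswith("chr") else chrom


def read_maf(path: str | Path) -> list[MutationRecord]:
    """Read somatic SNVs from a MAF-like TSV.

    Non-SNV rows (indels, multi-base alleles, ref == alt) are skipped with a
    logged count.  ``Hugo_Symbol`` and ``ref_context``/``context`` columns
    are honored when present.
    """
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        logger.warning("empty MAF file %s", path)
        return []
    for col in _MAF_REQUIRED:
        if col not in df.columns:
            raise FormatError(f"MAF {path} missing required column {col!r}")
    ctx_col = next((c for c in ("ref_context", "context") if c in df.columns), None)
    records: list[MutationRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        d = row._asdict()
        ref = str(d["Reference_Allele"]).upper()
        alt = str(d["Tumor_Seq_Allele2"]).upper()
        if ref not in _BASES or alt not in _BASES or ref == alt:
            skipped += 1
            continue
        ctx = None
        if ctx_col is not None:
            raw = d.get(ctx_col)
            if isinstance(raw, str) and len(raw) == 3 and raw.upper()[1] == ref:
                ctx = raw.upper()
        gene = d.get("Hugo_Symbol")
        records.append(
            MutationRecord(
                sample_id=str(d["Tumor_Sample_Barcode"]),
                chrom=_norm_chrom(d["Chromosome"]),
                pos=int(d["Start_Position"]),
                ref=ref,
                alt=alt,
                gene="" if not isinstance(gene, str) else gene,
                context=ctx,
            )
        )
    if skipped:
        logger.info("read_maf %s: skipped %d non-SNV rows", path, skipped)
    if not records and skipped == 0:
        logger.warning("MAF file %s contained no data rows", path)
    return records


def write_maf(records: list[MutationRecord], path: str | Path) -> None:
    rows = [
        {
            "Hugo_Symbol": r.gene,
            "Chromosome": r.chrom,
            "Start_Position": r.pos,
            "Reference_Allele": r.ref,
            "Tumor_Seq_Allele2": r.alt,
            "Tumor_Sample_Barcode": r.sample_id,
            "ref_context": r.context or "",
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path, sample_id: str) -> list[MutationRecord]:
    """Minimal VCF reader (CHROM POS ID REF ALT); one sample per file."""
    records: list[MutationRecord] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise FormatError(f"VCF {path}: short line {line!r}")
            chrom, pos, _, ref, alt = fields[:5]
            ref, alt = ref.upper(), alt.upper()
            if ref not in _BASES or alt not in _BASES or ref == alt:
                skipped += 1
                continue
            records.append(
                MutationRecord(sample_id, _norm_chrom(chrom), int(pos), ref, alt)
            )
    if skipped:
        logger.info("read_vcf %s: skipped %d non-SNV rows", path, skipped)
    return records


# ---------------------------------------------------------------------------
# Signature catalogs (COSMIC v2 TSV layout)

_CATALOG_META = ["Substitution Type", "Trinucleotide", "Somatic Mutation Type"]


def read_catalog(path: str | Path) -> SignatureCatalog:
    """Read a COSMIC-v2-layout signature TSV.

    Rows are reordered into the canonical channel order; each signature
    column is renormalized to sum 1 when off by at most 1e-3.
    """
    df = pd.read_csv(path, sep="\t")
    for col in _CATALOG_META:
        if col not in df.columns:
            raise FormatError(f"catalog {path} missing column {col!r}")
    if len(df) != 96:
        raise FormatError(f"catalog {path} has {len(df)} channel rows, expected 96")
    labels = df["Somatic Mutation Type"].tolist()
    if set(labels) != set(CHANNELS):
        raise FormatError(f"catalog {path} channel labels do not cover the 96 channels")
    df = df.set_index("Somatic Mutation Type").loc[list(CHANNELS)]
    sig_cols = [c for c in df.columns if c not in ("Substitution Type", "Trinucleotide")]
    if not sig_cols:
        raise FormatError(f"catalog {path} has no signature columns")
    mat = df[sig_cols].to_numpy(dtype=float).T
    if (mat < 0).any():
        raise FormatError(f"catalog {path} contains negative probabilities")
    sums = mat.sum(axis=1)
    off = np.abs(sums - 1)
    if (off > 1e-3 + 1e-12).any():
        bad = sig_cols[int(off.argmax())]
        raise FormatError(f"catalog {path}: column {bad!r} sums to {sums[off.argmax()]:.6f}")
    return SignatureCatalog(sig_cols, mat / sums[:, None])


def write_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    sub = [label[2:5] for label in CHANNELS]  # e.g. "C>A"
    tri = [label[0] + label[2] + label[6] for label in CHANNELS]  # e.g. "ACA"
    df = pd.DataFrame(
        {"Substitution Type": sub, "Trinucleotide": tri, "Somatic Mutation Type": CHANNELS}
    )
    for name, row in zip(catalog.names, catalog.matrix):
        df[name] = row
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# PPI edge lists


def read_edge_list(
    path: str | Path, min_confidence: float | None = None
) -> PPINetwork:
    """Read a two-column (optionally three: confidence) gene-symbol TSV.

    The edge set is undirected and deduplicated; self-loops are dropped.
    With ``min_confidence`` set, rows whose third column is below it are
    discarded (the STRING-style score filter; off by default).
    """
    edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0].strip() or not fields[1].strip():
                raise FormatError(f"edge list {path}:{lineno}: malformed row {line!r}")
            if min_confidence is not None and len(fields) >= 3:
                try:
                    conf = float(fields[2])
                except ValueError:
                    raise FormatError(
                        f"edge list {path}:{lineno}: non-numeric confidence {fields[2]!r}"
                    ) from None
                if conf < min_confidence:
                    continue
            edges.append((fields[0], fields[1]))
    return PPINetwork.from_edges(edges)


def write_edge_list(network: PPINetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in network.edges):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Exposures, spectra, gene matrices


def write_exposures(exposures: pd.DataFrame, path: str | Path) -> None:
    """samples x signatures TSV, sample ids in the first column."""
    exposures.to_csv(path, sep="\t", index_label="sample_id", float_format="%.10g")


def read_exposures(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def write_spectra(spectra: list[Spectrum96], path: str | Path) -> None:
    df = pd.DataFrame(
        [s.counts for s in spectra],
        index=pd.Index([s.sample_id for s in spectra], name="sample_id"),
        columns=list(CHANNELS),
    )
    df.to_csv(path, sep="\t")


def read_spectra(path: str | Path) -> list[Spectrum96]:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = [c for c in CHANNELS if c not in df.columns]
    if missing:
        raise FormatError(f"spectra table {path} missing channel columns {missing[:3]}...")
    return [
        Spectrum96(str(sid), row[list(CHANNELS)].to_numpy(dtype=np.int64))
        for sid, row in df.iterrows()
    ]


def write_gene_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    matrix.astype(int).to_csv(path, sep="\t", index_label="sample_id")


def read_gene_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    df.columns = [normalize_symbol(c) for c in df.columns]
    return df.astype(int)


# ---------------------------------------------------------------------------
# Model JSON


def write_model_json(model_dict: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(model_dict, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_model_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
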