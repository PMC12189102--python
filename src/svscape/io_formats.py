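"""Readers/writers for the external formats the pipeline touches.

Every coordinate is normalised at the boundary into a single internal
convention: 0-based, half-open.  VCF (1-based) and RepeatMasker ``.out``
(1-based inclusive) are converted exactly once at ingest; BED is already
0-based half-open.  Insertions are carried as zero-length anchor points
``[pos, pos)`` — an inserted sequence occupies no reference span — with the
inserted length stored separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1  # dosage code for a missing genotype

TRACK_COLUMNS = ["chrom", "start", "end", "label", "sublabel"]


class FormatError(ValueError):
    """Raised for malformed or inconsistent input files."""


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome names and lengths (bp)."""

    chrom_names: tuple[str, ...]
    chrom_lengths: dict[str, int]

    def __post_init__(self) -> None:
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise ValueError("duplicate chromosome names")
        for name in self.chrom_names:
            if self.chrom_lengths[name] <= 0:
                raise ValueError(f"chromosome {name} has non-positive length")

    @classmethod
    def from_pairs(cls, pairs) -> "GenomeLayout":
        pairs = list(pairs)
        return cls(tuple(n for n, _ in pairs), {n: int(l) for n, l in pairs})

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.chrom_lengths

    def __len__(self) -> int:
        return len(self.chrom_names)

    @property
    def total_length(self) -> int:
        return sum(self.chrom_lengths.values())


def read_genome_tsv(path) -> GenomeLayout:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "length"], dtype={"chrom": str})
    return GenomeLayout.from_pairs(zip(df["chrom"], df["length"]))


def write_genome_tsv(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for name in layout.chrom_names:
            fh.write(f"{name}\t{layout.chrom_lengths[name]}\n")


# ---------------------------------------------------------------------------
# Interval tracks
# ---------------------------------------------------------------------------

@dataclass
class IntervalTrack:
    """Labelled genomic intervals, 0-based half-open, sorted by (chrom, start).

    ``label`` carries the primary annotation (QTL trait category, repeat
    class/family, tissue); ``sublabel`` a secondary one (repeat name).
    """

    df: pd.DataFrame
    name: str = ""

    def __post_init__(self) -> None:
        df = self.df
        for col in TRACK_COLUMNS:
            if col not in df.columns:
                df[col] = "" if col in ("label", "sublabel") else None
        df = df[TRACK_COLUMNS].copy()
        if len(df) and (df["start"] >= df["end"]).any():
            bad = df.index[df["start"] >= df["end"]][0]
            raise FormatError(f"interval with start >= end at row {bad}")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        self.df = df

    @classmethod
    def from_records(cls, records, name: str = "") -> "IntervalTrack":
        """records: iterable of (chrom, start, end[, label[, sublabel]])."""
        rows = []
        for rec in records:
            rec = list(rec) + [""] * (5 - len(rec))
            rows.append(rec[:5])
        df = pd.DataFrame(rows, columns=TRACK_COLUMNS) if rows else pd.DataFrame(
            columns=TRACK_COLUMNS)
        return cls(df, name=name)

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, mask) -> "IntervalTrack":
        return IntervalTrack(self.df[mask].reset_index(drop=True), name=self.name)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome sorted (starts, ends)."""
        out = {}
        for chrom, grp in self.df.groupby("chrom", sort=False):
            out[str(chrom)] = (grp["start"].to_numpy(), grp["end"].to_numpy())
        return out

    def labels(self) -> list[str]:
        return sorted(self.df["label"].unique())


def read_bed(path, name: str = "", label_col: int = 3, sublabel_col: int | None = None
             ) -> IntervalTrack:
    """Read a BED3+ file; optional label/sublabel taken from the given columns."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: malformed coordinate") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end")
            label = parts[label_col] if label_col is not None and len(parts) > label_col else ""
            sub = parts[sublabel_col] if sublabel_col is not None and len(parts) > sublabel_col else ""
            rows.append((chrom, start, end, label, sub))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS) if rows else pd.DataFrame(columns=TRACK_COLUMNS)
    return IntervalTrack(df, name=name or str(path))


def write_bed(track: IntervalTrack, path) -> None:
    """Write BED with label in column 4 and sublabel in column 5 when present."""
    with open(path, "w") as fh:
        for row in track.df.itertuples(index=False):
            fields = [row.chrom, str(row.start), str(row.end)]
            if row.label or row.sublabel:
                fields.append(str(row.label))
            if row.sublabel:
                fields.append(str(row.sublabel))
            fh.write("\t".join(fields) + "\n")


def read_repeatmasker_out(path, name: str = "repeats") -> IntervalTrack:
    """Parse a RepeatMasker ``.out`` file into an IntervalTrack.

    Query begin/end are 1-based inclusive and converted to 0-based half-open.
    ``label`` is the repeat class/family (column 11, e.g. "LINE/L1"),
    ``sublabel`` the repeat name (column 10, e.g. "BOV-A2").  Truncated rows
    are skipped with a warning.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            # header lines start with "SW"/"score" or "There were no ..."
            if not parts[0].lstrip("-").isdigit():
                continue
            if len(parts) < 11:
                log.warning("%s:%d: truncated RepeatMasker row skipped", path, lineno)
                continue
            try:
                chrom = parts[4]
                qbegin, qend = int(parts[5]), int(parts[6])
                rep_name, rep_class = parts[9], parts[10]
            except ValueError:
                log.warning("%s:%d: unparseable RepeatMasker row skipped", path, lineno)
                continue
            rows.append((chrom, qbegin - 1, qend, rep_class, rep_name))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS) if rows else pd.DataFrame(columns=TRACK_COLUMNS)
    return IntervalTrack(df, name=name)


# ---------------------------------------------------------------------------
# Variant tables
# ---------------------------------------------------------------------------

VARIANT_COLUMNS = ["id", "chrom", "pos", "start", "end", "vtype", "length", "ref", "alt", "qual"]


@dataclass
class VariantTable:
    """A cohort of biallelic variants with per-sample allele dosages.

    ``df`` columns: id, chrom, pos (original 1-based VCF POS), start/end
    (internal 0-based half-open span; ``[a, a)`` anchor for insertions),
    vtype in {SNP, INS, DEL}, length (bp; |len(REF)-len(ALT)| or SVLEN),
    ref, alt, qual.  ``dosages`` is an (n_variants, n_samples) int16 matrix
    of alt-allele counts with -1 for missing.  ``info`` is a per-variant
    dict of INFO fields.
    """

    df: pd.DataFrame
    dosages: np.ndarray
    samples: list[str]
    info: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.df) != len(self.dosages):
            raise ValueError("df and dosage matrix disagree on variant count")
        if self.dosages.ndim != 2 or self.dosages.shape[1] != len(self.samples):
            raise ValueError("dosage matrix shape does not match samples")
        if not self.info:
            self.info = [{} for _ in range(len(self.df))]
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset(self, mask) -> "VariantTable":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return VariantTable(
            self.df.iloc[idx].reset_index(drop=True),
            self.dosages[idx],
            self.samples,
            [self.info[i] for i in idx],
        )

    def where(self, **kwargs) -> "VariantTable":
        mask = np.ones(len(self), dtype=bool)
        for col, val in kwargs.items():
            if isinstance(val, (list, tuple, set)):
                mask &= self.df[col].isin(list(val)).to_numpy()
            else:
                mask &= (self.df[col] == val).to_numpy()
        return self.subset(mask)


def _classify_alleles(ref: str, alt: str) -> tuple[str, int]:
    """(vtype, length) from REF/ALT strings; handles symbolic <INS>/<DEL>."""
    if alt in ("<INS>", "<DEL>"):
        return alt[1:-1], 0  # length resolved from SVLEN/END by the caller
    if len(ref) == len(alt):
        if len(ref) != 1:
            raise FormatError(f"unsupported balanced substitution {ref}>{alt}")
        return "SNP", 1
    if len(alt) > len(ref):
        return "INS", len(alt) - len(ref)
    return "DEL", len(ref) - len(alt)


def read_vcf(path, layout: GenomeLayout | None = None, sample_subset=None,
             multiallelic: str = "error") -> VariantTable:
    """Read a VCF 4.x into a :class:`VariantTable` via cyvcf2.

    Records are typed INS/DEL/SNP by REF/ALT length comparison, with
    SVLEN/END honoured when present; genotypes become alt-allele dosages
    with missing preserved as -1.  An unsorted file or a chromosome absent
    from ``layout`` raises; multiallelic records raise or are skipped per
    ``multiallelic`` in {"error", "skip"}.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("error", "skip"):
        raise ValueError("multiallelic must be 'error' or 'skip'")
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if sample_subset is not None:
        keep = [i for i, s in enumerate(samples) if s in set(sample_subset)]
        missing = set(sample_subset) - set(samples)
        if missing:
            raise FormatError(f"samples not in VCF: {sorted(missing)}")
    else:
        keep = list(range(len(samples)))
    out_samples = [samples[i] for i in keep]
    keep = np.array(keep, dtype=int)

    rows, infos, dosage_rows = [], [], []
    last_pos: dict[str, int] = {}
    seen_done: set[str] = set()
    prev_chrom = None
    for i, rec in enumerate(vcf):
        chrom = rec.CHROM
        if layout is not None and chrom not in layout:
            raise FormatError(f"chromosome {chrom} not in genome layout")
        if chrom != prev_chrom:
            if chrom in seen_done:
                raise FormatError(f"VCF not sorted: chromosome {chrom} appears twice")
            if prev_chrom is not None:
                seen_done.add(prev_chrom)
            prev_chrom = chrom
        if rec.POS < last_pos.get(chrom, 0):
            raise FormatError(f"VCF not sorted at {chrom}:{rec.POS}")
        last_pos[chrom] = rec.POS
        if len(rec.ALT) != 1:
            if multiallelic == "error":
                raise FormatError(f"multiallelic record at {chrom}:{rec.POS}")
            continue
        ref, alt = rec.REF, rec.ALT[0]
        vtype, length = _classify_alleles(ref, alt)
        info = dict(rec.INFO)
        pos = rec.POS
        pos0 = pos - 1
        if vtype in ("INS", "DEL"):
            svlen = info.get("SVLEN")
            if isinstance(svlen, (tuple, list)):
                svlen = svlen[0]
            if svlen is not None:
                length = abs(int(svlen))
            end_info = info.get("END")
            if vtype == "DEL":
                # deleted span excludes the padding base at POS
                start = pos0 + (1 if alt.startswith("<") else len(alt))
                if end_info is not None:
                    end = int(end_info)
                    if length == 0:
                        length = end - start
                else:
                    end = start + length
            else:  # INS: zero-length anchor just after the padding base
                anchor = pos0 + (len(ref) if not alt.startswith("<") else 1)
                start = end = anchor
            if length < 1:
                raise FormatError(f"cannot resolve length of SV at {chrom}:{pos}")
        else:
            start, end = pos0, pos0 + 1
        if layout is not None and end > layout.chrom_lengths[chrom]:
            raise FormatError(f"variant at {chrom}:{pos} extends past chromosome end")
        vid = rec.ID if rec.ID not in (None, ".") else f"{chrom}_{pos}_{vtype}"
        qual = float(rec.QUAL) if rec.QUAL is not None else np.nan
        # gts012: 0 hom-ref, 1 het, 2 hom-alt, 3 unknown
        gts = np.asarray(rec.gt_types)[keep].astype(np.int16)
        gts[gts == 3] = MISSING
        rows.append((vid, chrom, pos, start, end, vtype, length, ref, alt, qual))
        infos.append(info)
        dosage_rows.append(gts)
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS) if rows else pd.DataFrame(
        columns=VARIANT_COLUMNS)
    dosages = (np.vstack(dosage_rows) if dosage_rows
               else np.zeros((0, len(out_samples)), dtype=np.int16))
    return VariantTable(df, dosages, out_samples, infos)


_INFO_HEADERS = {
    "SVTYPE": ("1", "String", "Type of structural variant"),
    "SVLEN": ("1", "Integer", "Length of structural variant"),
    "END": ("1", "Integer", "End position (1-based inclusive)"),
    "QD": ("1", "Float", "QualByDepth"),
    "FS": ("1", "Float", "FisherStrand"),
    "SOR": ("1", "Float", "StrandOddsRatio"),
    "MQ": ("1", "Float", "RMSMappingQuality"),
    "MQRankSum": ("1", "Float", "MappingQualityRankSumTest"),
    "ReadPosRankSum": ("1", "Float", "ReadPosRankSumTest"),
}

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(table: VariantTable, path, layout: GenomeLayout | None = None) -> None:
    """Write a VariantTable back to a sorted VCF 4.2 text file."""
    if layout is not None:
        rank = {c: i for i, c in enumerate(layout.chrom_names)}
        chrom_key = table.df["chrom"].map(rank).to_numpy()
    else:
        chrom_key = table.df["chrom"].astype("category").cat.codes.to_numpy()
    order = np.lexsort((table.df["pos"].to_numpy(), chrom_key))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=svscape\n")
        if layout is not None:
            for name in layout.chrom_names:
                fh.write(f"##contig=<ID={name},length={layout.chrom_lengths[name]}>\n")
        for key, (num, typ, desc) in _INFO_HEADERS.items():
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples) + "\n")
        for i in order:
            row = table.df.iloc[i]
            info = table.info[i]
            parts = []
            for key, val in info.items():
                if val is True:
                    parts.append(key)
                elif isinstance(val, float):
                    parts.append(f"{key}={val:g}")
                else:
                    parts.append(f"{key}={val}")
            info_str = ";".join(parts) if parts else "."
            qual = "." if pd.isna(row.qual) else f"{row.qual:g}"
            gts = "\t".join(_GT_STRINGS[int(d)] for d in table.dosages[i])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t"
                     f"{qual}\tPASS\t{info_str}\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

CODING_TX_TYPES = {"mRNA", "transcript"}


@dataclass
class GeneModelSet:
    """gene/transcript/exon/UTR hierarchy from a GFF3, 0-based half-open.

    ``genes``: DataFrame(gene_id, chrom, start, end, strand, biotype);
    ``transcripts``: DataFrame(tx_id, gene_id, chrom, strand, tx_type);
    ``exons``/``utr5``/``utr3``: dict tx_id -> list of (start, end).
    Introns are derived as the gaps between consecutive exons.
    """

    genes: pd.DataFrame
    transcripts: pd.DataFrame
    exons: dict[str, list[tuple[int, int]]]
    utr5: dict[str, list[tuple[int, int]]]
    utr3: dict[str, list[tuple[int, int]]]

    def introns(self, tx_id: str) -> list[tuple[int, int]]:
        ex = sorted(self.exons.get(tx_id, []))
        return [(ex[i][1], ex[i + 1][0]) for i in range(len(ex) - 1)
                if ex[i + 1][0] > ex[i][1]]

    def gene_track(self) -> IntervalTrack:
        df = self.genes.rename(columns={"gene_id": "label"})[
            ["chrom", "start", "end", "label"]].copy()
        df["sublabel"] = self.genes["biotype"].to_numpy()
        return IntervalTrack(df, name="genes")

    def is_coding_tx(self, tx_id: str) -> bool:
        row = self.transcripts.loc[self.transcripts["tx_id"] == tx_id]
        return bool(len(row)) and row.iloc[0]["tx_type"] in CODING_TX_TYPES


def read_gff_genes(path) -> GeneModelSet:
    """Read gene models from a GFF3 file (1-based inclusive -> half-open).

    Exons without a resolvable parent transcript get a synthetic singleton
    transcript (with a warning); genes without transcript children are kept
    as gene-level intervals only.
    """
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    genes, txs = [], []
    exons: dict[str, list[tuple[int, int]]] = {}
    utr5: dict[str, list[tuple[int, int]]] = {}
    utr3: dict[str, list[tuple[int, int]]] = {}

    gene_types = {"gene", "ncRNA_gene", "pseudogene"}
    tx_types = {"mRNA", "transcript", "lnc_RNA", "ncRNA", "miRNA", "snoRNA",
                "rRNA", "tRNA", "pseudogenic_transcript"}
    for feat in db.all_features():
        if feat.featuretype in gene_types:
            biotype = feat.attributes.get("biotype", [
                "protein_coding" if feat.featuretype == "gene" else feat.featuretype])[0]
            genes.append((feat.id, feat.seqid, feat.start - 1, feat.end,
                          feat.strand, biotype))
        elif feat.featuretype in tx_types:
            parents = [p.id for p in db.parents(feat, level=1)]
            gene_id = parents[0] if parents else feat.id
            txs.append((feat.id, gene_id, feat.seqid, feat.strand, feat.featuretype))
        elif feat.featuretype == "exon":
            parents = [p.id for p in db.parents(feat, level=1)]
            if not parents:
                warnings.warn(f"exon {feat.id} has no parent; synthetic transcript created")
                tx_id = f"tx_orphan_{feat.seqid}_{feat.start}"
                txs.append((tx_id, tx_id, feat.seqid, feat.strand, "transcript"))
                parents = [tx_id]
            for p in parents:
                exons.setdefault(p, []).append((feat.start - 1, feat.end))
        elif feat.featuretype in ("five_prime_UTR", "three_prime_UTR"):
            target = utr5 if feat.featuretype == "five_prime_UTR" else utr3
            for p in db.parents(feat, level=1):
                target.setdefault(p.id, []).append((feat.start - 1, feat.end))

    genes_df = pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                            "strand", "biotype"])
    tx_df = pd.DataFrame(txs, columns=["tx_id", "gene_id", "chrom", "strand", "tx_type"])
    for d in (exons, utr5, utr3):
        for k in d:
            d[k] = sorted(d[k])
    return GeneModelSet(genes_df, tx_df, exons, utr5, utr3)
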