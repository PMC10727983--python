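"""Repeat-aware feature catalogs.

Builds a unified feature namespace over annotated genes and genomic repeat
insertions.  Individual repeat insertions (millions genome-wide) are mapped
many-to-one onto their RepeatMasker subfamily, so that downstream
quantification sees one tractable feature per subfamily (e.g. ``rmsk:AluY``)
next to ordinary gene features.  Three catalog modes are supported:

``repeat_naive``
    genes only — the conventional annotation.
``repeat_aware``
    genes plus one feature per repeat subfamily.
``repeat_alone``
    repeat subfamilies only.

Coordinates are 0-based half-open internally.  RepeatMasker tables (UCSC
``rmsk`` dialect) already store genoStart/genoEnd that way; GTF input is
1-based inclusive and converted on parse.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from pyfaidx import Fasta

logger = logging.getLogger(__name__)

CATALOG_MODES = ("repeat_naive", "repeat_aware", "repeat_alone")

#: prefix that namespaces repeat-subfamily features away from gene ids
REPEAT_PREFIX = "rmsk:"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RepeatInstance:
    """One genomic repeat insertion with its three-level RepeatMasker labels."""

    instance_id: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str  # "+" or "-"
    subfamily: str  # repName, e.g. "AluY" or "(TA)n"
    family: str  # repFamily, e.g. "Alu"
    superfamily: str  # repClass with trailing "?" stripped, e.g. "SINE"
    raw_superfamily: str = ""  # repClass as stored, e.g. "SINE?"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(
                f"repeat instance {self.instance_id}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"repeat instance {self.instance_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneRecord:
    """An annotated gene and its transcripts."""

    gene_id: str
    gene_name: str
    biotype: str
    transcript_ids: list[str] = field(default_factory=list)


@dataclass
class Feature:
    feature_id: str
    feature_class: str  # "gene" | "repeat_subfamily"
    group: str  # biotype for genes, superfamily for repeats
    display_name: str


@dataclass
class FeatureCatalog:
    """Unified namespace of gene and repeat-subfamily features.

    ``unit_to_feature`` maps every quantification unit (a transcript id or a
    repeat instance id) onto exactly one feature id.
    """

    features: list[Feature]
    unit_to_feature: dict[str, str]
    mode: str

    def __post_init__(self):
        if self.mode not in CATALOG_MODES:
            raise ValueError(f"unknown catalog mode {self.mode!r}")
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate feature_id in catalog")

    @property
    def feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features]

    def group_of(self) -> dict[str, str]:
        """feature_id -> group (biotype or repeat superfamily)."""
        return {f.feature_id: f.group for f in self.features}

    def class_of(self) -> dict[str, str]:
        return {f.feature_id: f.feature_class for f in self.features}

    def repeat_feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features if f.feature_class == "repeat_subfamily"]

    def gene_feature_ids(self) -> list[str]:
        return [f.feature_id for f in self.features if f.feature_class == "gene"]

    # ---- persistence ---------------------------------------------------

    def write_t2g(self, path: Union[str, Path]) -> None:
        """Write the unit->feature map as a two-column TSV (t2g analog)."""
        with open(path, "w") as fh:
            for unit, feat in self.unit_to_feature.items():
                fh.write(f"{unit}\t{feat}\n")

    def summary(self) -> dict:
        per_class: dict[str, int] = {}
        per_group: dict[str, int] = {}
        for f in self.features:
            per_class[f.feature_class] = per_class.get(f.feature_class, 0) + 1
            per_group[f.group] = per_group.get(f.group, 0) + 1
        return {
            "mode": self.mode,
            "n_features": len(self.features),
            "n_units": len(self.unit_to_feature),
            "features_per_class": per_class,
            "features_per_group": per_group,
        }

    def write_summary(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)

    def write_features(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            fh.write("feature_id\tfeature_class\tgroup\tdisplay_name\n")
            for f in self.features:
                fh.write(f"{f.feature_id}\t{f.feature_class}\t{f.group}\t{f.display_name}\n")


def read_t2g(path: Union[str, Path]) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            unit, feat = line.split("\t")
            out[unit] = feat
    return out


def read_features_table(path: Union[str, Path]) -> list[Feature]:
    feats = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("feature_id")
        for line in fh:
            fid, fclass, group, name = line.rstrip("\n").split("\t")
            feats.append(Feature(fid, fclass, group, name))
    return feats


# ---------------------------------------------------------------------------
# rmsk parsing


class MalformedRowError(ValueError):
    pass


_RMSK_COLUMNS = ("genoName", "genoStart", "genoEnd", "strand", "repName", "repClass", "repFamily")


def make_instance_id(subfamily: str, chrom: str, start: int, end: int, strand: str) -> str:
    return f"{subfamily}:{chrom}:{start}-{end}({strand})"


def parse_rmsk(stream: Union[str, Path, IO[str], Iterable[str]]) -> list[RepeatInstance]:
    """Parse a RepeatMasker table in the UCSC rmsk TSV dialect.

    Required columns: genoName, genoStart, genoEnd, strand, repName,
    repClass, repFamily.  A header row is optional; a leading ``bin`` column
    is tolerated.  rmsk's "C" strand (complement) is normalized to "-".
    Rows whose genoStart >= genoEnd are rejected with a warning and counted;
    structurally malformed rows raise with the offending line number.
    """
    close = False
    if isinstance(stream, (str, Path)):
        stream = open(stream)
        close = True
    try:
        lines = iter(stream)
        instances: list[RepeatInstance] = []
        rejected = 0
        col_idx: dict[str, int] | None = None
        for lineno, raw in enumerate(lines, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if col_idx is None:
                if "genoName" in parts:  # header row
                    col_idx = {c: parts.index(c) for c in _RMSK_COLUMNS if c in parts}
                    missing = set(_RMSK_COLUMNS) - set(col_idx)
                    if missing:
                        raise MalformedRowError(
                            f"line {lineno}: rmsk header missing columns {sorted(missing)}"
                        )
                    continue
                # headerless: standard UCSC order, optional leading bin column
                offset = 1 if parts and re.fullmatch(r"\d+", parts[0]) and len(parts) >= 8 else 0
                col_idx = {
                    "genoName": offset + 0,
                    "genoStart": offset + 1,
                    "genoEnd": offset + 2,
                    "strand": offset + 3,
                    "repName": offset + 4,
                    "repClass": offset + 5,
                    "repFamily": offset + 6,
                }
            try:
                chrom = parts[col_idx["genoName"]]
                start = int(parts[col_idx["genoStart"]])
                end = int(parts[col_idx["genoEnd"]])
                strand = parts[col_idx["strand"]]
                subfamily = parts[col_idx["repName"]]
                repclass = parts[col_idx["repClass"]]
                repfamily = parts[col_idx["repFamily"]]
            except (IndexError, ValueError) as exc:
                raise MalformedRowError(f"line {lineno}: malformed rmsk row: {exc}") from exc
            if strand == "C":
                strand = "-"
            if strand not in ("+", "-"):
                raise MalformedRowError(f"line {lineno}: bad strand {strand!r}")
            if start >= end:
                logger.warning("line %d: genoStart %d >= genoEnd %d, row rejected", lineno, start, end)
                rejected += 1
                continue
            instances.append(
                RepeatInstance(
                    instance_id=make_instance_id(subfamily, chrom, start, end, strand),
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    subfamily=subfamily,
                    family=repfamily,
                    superfamily=repclass.rstrip("?"),
                    raw_superfamily=repclass,
                )
            )
        if rejected:
            logger.warning("parse_rmsk: rejected %d rows with non-positive length", rejected)
        return instances
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# GTF parsing

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


def _gtf_attrs(field9: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field9))


def parse_gtf_genes(stream: Union[str, Path, IO[str], Iterable[str]]) -> list[GeneRecord]:
    """Parse gene and transcript records from a GENCODE-dialect GTF.

    The parse is order-independent: a transcript line may precede its gene
    line.  A transcript whose gene_id never appears on a gene line is an
    error; a gene without gene_type gets biotype "unknown" with a warning.
    """
    close = False
    if isinstance(stream, (str, Path)):
        stream = open(stream)
        close = True
    try:
        genes: dict[str, GeneRecord] = {}
        pending_tx: dict[str, list[str]] = {}  # gene_id -> transcript ids seen early
        for raw in stream:
            if raw.startswith("#"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            feature_type = parts[2]
            if feature_type not in ("gene", "transcript"):
                continue
            attrs = _gtf_attrs(parts[8])
            gene_id = attrs.get("gene_id")
            if gene_id is None:
                raise ValueError("GTF record without gene_id attribute")
            if feature_type == "gene":
                biotype = attrs.get("gene_type")
                if biotype is None:
                    logger.warning("gene %s has no gene_type; biotype set to 'unknown'", gene_id)
                    biotype = "unknown"
                rec = GeneRecord(
                    gene_id=gene_id,
                    gene_name=attrs.get("gene_name", gene_id),
                    biotype=biotype,
                )
                if gene_id in genes:
                    raise ValueError(f"duplicate gene record for {gene_id}")
                rec.transcript_ids.extend(pending_tx.pop(gene_id, []))
                genes[gene_id] = rec
            else:  # transcript
                tx_id = attrs.get("transcript_id")
                if tx_id is None:
                    raise ValueError(f"transcript record for gene {gene_id} without transcript_id")
                if gene_id in genes:
                    genes[gene_id].transcript_ids.append(tx_id)
                else:
                    pending_tx.setdefault(gene_id, []).append(tx_id)
        if pending_tx:
            raise ValueError(
                f"transcripts reference unknown gene_ids: {sorted(pending_tx)}"
            )
        return list(genes.values())
    finally:
        if close:
            stream.close()


# ---------------------------------------------------------------------------
# catalog construction


def build_catalog(
    genes: list[GeneRecord] | None,
    instances: list[RepeatInstance] | None,
    mode: str = "repeat_aware",
) -> FeatureCatalog:
    """Assemble the feature catalog for the requested mode.

    Gene features are keyed by gene_id and grouped by biotype; repeat
    features are keyed ``rmsk:<subfamily>`` and grouped by superfamily
    (repClass).  Every transcript maps to its gene feature and every repeat
    instance to its subfamily feature.
    """
    if mode not in CATALOG_MODES:
        raise ValueError(f"unknown catalog mode {mode!r}")
    genes = genes or []
    instances = instances or []
    want_genes = mode in ("repeat_naive", "repeat_aware")
    want_repeats = mode in ("repeat_aware", "repeat_alone")
    if want_genes and not genes:
        raise ValueError(f"mode {mode!r} requires gene records, none given")
    if want_repeats and not instances:
        raise ValueError(f"mode {mode!r} requires repeat instances, none given")

    features: list[Feature] = []
    unit_to_feature: dict[str, str] = {}

    if want_genes:
        seen: set[str] = set()
        for g in genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            features.append(Feature(g.gene_id, "gene", g.biotype, g.gene_name))
            for tx in g.transcript_ids:
                if tx in unit_to_feature:
                    raise ValueError(f"transcript {tx} assigned to two genes")
                unit_to_feature[tx] = g.gene_id

    if want_repeats:
        subfam_super: dict[str, str] = {}
        for inst in instances:
            subfam_super.setdefault(inst.subfamily, inst.superfamily)
            unit_to_feature[inst.instance_id] = REPEAT_PREFIX + inst.subfamily
        for subfam in sorted(subfam_super):
            features.append(
                Feature(REPEAT_PREFIX + subfam, "repeat_subfamily", subfam_super[subfam], subfam)
            )

    return FeatureCatalog(features=features, unit_to_feature=unit_to_feature, mode=mode)


# ---------------------------------------------------------------------------
# sequence extraction


@dataclass(frozen=True)
class CatalogUnit:
    """A catalog unit with genomic coordinates, used for sequence extraction."""

    unit_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"


def units_from_instances(instances: Iterable[RepeatInstance]) -> list[CatalogUnit]:
    return [
        CatalogUnit(i.instance_id, i.chrom, i.start, i.end, i.strand) for i in instances
    ]


def extract_sequences(
    genome: Union[str, Path, Fasta, dict],
    units: Iterable[CatalogUnit],
) -> Iterator[tuple[str, str]]:
    """Yield (unit_id, sequence) for each unit; minus strand reverse-complemented.

    ``genome`` may be a FASTA path (indexed access via pyfaidx), an open
    :class:`pyfaidx.Fasta`, or a plain dict of chrom -> sequence string.
    """
    if isinstance(genome, (str, Path)):
        genome = Fasta(str(genome))
    units = list(units)
    if isinstance(genome, dict):
        available = set(genome)
        fetch = lambda c, s, e: genome[c][s:e]
        length_of = lambda c: len(genome[c])
    else:
        available = set(genome.keys())
        fetch = lambda c, s, e: str(genome[c][s:e])
        length_of = lambda c: len(genome[c])
    missing = sorted({u.chrom for u in units} - available)
    if missing:
        raise KeyError(f"chromosomes absent from genome: {missing}")
    for u in units:
        if u.start < 0 or u.end > length_of(u.chrom):
            raise ValueError(
                f"unit {u.unit_id}: interval {u.start}-{u.end} out of bounds for {u.chrom}"
            )
        seq = fetch(u.chrom, u.start, u.end)
        if u.strand == "-":
            seq = reverse_complement(seq)
        yield u.unit_id, seq


def write_fasta(records: Iterable[tuple[str, str]], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: Union[str, Path]) -> dict[str, str]:
    """Load a small FASTA entirely into memory (test/fixture scale)."""
    out: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out[name] = "".join(chunks)
                name = line[1:].split()[0]
                chunks = []
            else:
                chunks.append(line)
    if name is not None:
        out[name] = "".join(chunks)
    return out
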