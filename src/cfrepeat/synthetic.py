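"""Synthetic fixtures for the whole pipeline.

Everything the other modules consume can be generated here at desk scale:

* a toy genome with planted, mutated copies of per-subfamily repeat
  consensus sequences (Alu-like ~300 nt by default) plus toy genes with
  1-3 transcripts, emitted as FASTA + rmsk TSV + GTF;
* a toy exact-substring quantifier standing in for a transcriptome
  quantifier: each read is assigned to the reference units containing it
  verbatim, multi-hit reads split fractionally;
* negative-binomial count cohorts with log-normal library sizes, planted
  condition fold changes on chosen features, and additive covariate effects
  on the log scale, with a matching clinical metadata table;
* long-read fragment sets with per-group Gaussian-mixture template lengths
  (the SINE default is bimodal: full-length ~300 nt and half-length ~150 nt
  species) placed at planted instance coordinates.

All randomness flows from one seed; per-stage child generators are derived
deterministically, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .annotation import (
    CatalogUnit,
    FeatureCatalog,
    GeneRecord,
    RepeatInstance,
    build_catalog,
    extract_sequences,
    make_instance_id,
    reverse_complement,
    units_from_instances,
    write_fasta,
)
from .lengths import AlignedFragment
from .quantify import QuantTable

BASES = np.array(list("ACGT"))

#: default per-group fragment-length mixtures: (weight, mean, sd)
DEFAULT_FRAGMENT_SPECS: dict[str, list[tuple[float, float, float]]] = {
    "SINE": [(0.5, 300.0, 20.0), (0.5, 150.0, 15.0)],
    "LINE": [(1.0, 258.0, 40.0)],
    "LTR": [(1.0, 167.0, 30.0)],
    "protein_coding": [(1.0, 456.0, 60.0)],
    "lncRNA": [(1.0, 303.0, 50.0)],
}


@dataclass
class SimulationConfig:
    """Study-condition knobs for all synthetic fixtures."""

    seed: int
    # cohort
    n_healthy: int = 30
    n_case: int = 30
    # catalog scale
    n_genes: int = 40
    n_subfamilies: int = 4
    instances_per_subfamily: int = 5
    # genome
    chrom_length: int = 30_000
    consensus_length: int = 300
    gene_length: int = 500
    mutation_rate: float = 0.03
    # counts
    dispersion: float = 0.3
    base_mean_log_mu: float = 4.0
    base_mean_log_sd: float = 1.0
    library_log_sd: float = 0.3
    planted_up: list[tuple[str, float]] = field(default_factory=list)  # (feature_id, log2fc)
    covariate_sd: float = 0.0  # sd of per-feature covariate coefficients (log scale)
    # fragments
    fragment_specs: dict[str, list[tuple[float, float, float]]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_FRAGMENT_SPECS.items()}
    )
    fragments_per_group: int = 500

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage child generator."""
        return np.random.default_rng([self.seed, stage])


# ---------------------------------------------------------------------------
# toy genome


@dataclass
class ToyGenome:
    genome: dict[str, str]
    instances: list[RepeatInstance]
    genes: list[GeneRecord]
    transcript_units: list[CatalogUnit]
    consensus: dict[str, str]

    def unit_sequences(self, which: str = "all") -> dict[str, str]:
        """Reference sequences for quantification units.

        which: "all" (transcripts + repeat instances), "genes", "repeats".
        """
        units: list[CatalogUnit] = []
        if which in ("all", "genes"):
            units += self.transcript_units
        if which in ("all", "repeats"):
            units += units_from_instances(self.instances)
        return dict(extract_sequences(self.genome, units))


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    arr = np.array(list(seq))
    hit = rng.random(len(arr)) < rate
    if hit.any():
        arr[hit] = rng.choice(BASES, size=int(hit.sum()))
    return "".join(arr)


def make_toy_genome(cfg: SimulationConfig) -> ToyGenome:
    """Build a single-chromosome toy genome with planted repeats and genes.

    Subfamily consensus sequences are random; planted copies are mutated at
    ``cfg.mutation_rate`` per base and placed non-overlapping on either
    strand.  Genes are intervals carrying 1-3 transcripts (the transcripts
    reuse the gene interval with small 5' truncations).
    """
    rng = cfg.rng(stage=1)
    chrom = "chrT"
    n_inst = cfg.n_subfamilies * cfg.instances_per_subfamily
    needed = n_inst * cfg.consensus_length + cfg.n_genes * cfg.gene_length
    length = max(cfg.chrom_length, int(needed * 2.5))
    seq = list(_random_seq(rng, length))

    # non-overlapping slots for instances and genes
    slot_sizes = [cfg.consensus_length] * n_inst + [cfg.gene_length] * cfg.n_genes
    total = sum(slot_sizes)
    gaps = rng.multinomial(length - total, np.ones(len(slot_sizes) + 1) / (len(slot_sizes) + 1))
    order = rng.permutation(len(slot_sizes))
    starts: list[int] = []
    pos = 0
    for k, slot_idx in enumerate(order):
        pos += gaps[k]
        starts.append(pos)
        pos += slot_sizes[slot_idx]
    slot_start = dict(zip(order, starts))

    # subfamily consensus and planted instances
    superfams = ["SINE", "LINE", "LTR", "Simple_repeat"]
    families = {"SINE": "Alu", "LINE": "L1", "LTR": "ERVL", "Simple_repeat": "Simple_repeat"}
    consensus: dict[str, str] = {}
    instances: list[RepeatInstance] = []
    slot = 0
    for s in range(cfg.n_subfamilies):
        sf = superfams[s % len(superfams)]
        name = f"{'Alu' if sf == 'SINE' else sf}_sf{s}"
        consensus[name] = _random_seq(rng, cfg.consensus_length)
        for _ in range(cfg.instances_per_subfamily):
            start = slot_start[slot]
            slot += 1
            end = start + cfg.consensus_length
            strand = "+" if rng.random() < 0.5 else "-"
            copy = _mutate(rng, consensus[name], cfg.mutation_rate)
            planted = copy if strand == "+" else reverse_complement(copy)
            seq[start:end] = list(planted)
            instances.append(
                RepeatInstance(
                    instance_id=make_instance_id(name, chrom, start, end, strand),
                    chrom=chrom,
                    start=start,
                    end=end,
                    strand=strand,
                    subfamily=name,
                    family=families[sf],
                    superfamily=sf,
                    raw_superfamily=sf,
                )
            )

    # genes and transcripts
    genes: list[GeneRecord] = []
    transcript_units: list[CatalogUnit] = []
    biotypes = ["protein_coding", "lncRNA"]
    for g in range(cfg.n_genes):
        start = slot_start[slot]
        slot += 1
        end = start + cfg.gene_length
        gid = f"GENE{g:04d}"
        rec = GeneRecord(gene_id=gid, gene_name=f"Toy{g}", biotype=biotypes[g % 2])
        n_tx = int(rng.integers(1, 4))
        for t in range(n_tx):
            tid = f"{gid}.T{t}"
            trunc = int(rng.integers(0, cfg.gene_length // 4)) if t > 0 else 0
            rec.transcript_ids.append(tid)
            transcript_units.append(CatalogUnit(tid, chrom, start + trunc, end, "+"))
        genes.append(rec)

    return ToyGenome(
        genome={chrom: "".join(seq)},
        instances=instances,
        genes=genes,
        transcript_units=transcript_units,
        consensus=consensus,
    )


def write_toy_genome(toy: ToyGenome, outdir: Union[str, Path]) -> dict[str, Path]:
    """Emit genome FASTA, rmsk TSV and GTF consumable by the annotation module."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "rmsk": outdir / "rmsk.tsv",
        "gtf": outdir / "genes.gtf",
    }
    write_fasta(toy.genome.items(), paths["genome"])
    with open(paths["rmsk"], "w") as fh:
        fh.write("genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n")
        for i in toy.instances:
            fh.write(
                f"{i.chrom}\t{i.start}\t{i.end}\t{i.strand}\t{i.subfamily}\t"
                f"{i.raw_superfamily}\t{i.family}\n"
            )
    tx_coords = {u.unit_id: u for u in toy.transcript_units}
    with open(paths["gtf"], "w") as fh:
        for g in toy.genes:
            tx_units = [tx_coords[t] for t in g.transcript_ids]
            gstart = min(u.start for u in tx_units)
            gend = max(u.end for u in tx_units)
            attrs = f'gene_id "{g.gene_id}"; gene_type "{g.biotype}"; gene_name "{g.gene_name}";'
            fh.write(
                f"{tx_units[0].chrom}\ttoy\tgene\t{gstart + 1}\t{gend}\t.\t+\t.\t{attrs}\n"
            )
            for u in tx_units:
                tattrs = attrs + f' transcript_id "{u.unit_id}";'
                fh.write(
                    f"{u.chrom}\ttoy\ttranscript\t{u.start + 1}\t{u.end}\t.\t+\t.\t{tattrs}\n"
                )
    return paths


# ---------------------------------------------------------------------------
# toy quantifier


def toy_quantify(
    reads: Sequence[str],
    reference: Mapping[str, str],
    sample_id: str = "sample",
) -> QuantTable:
    """Assign each read to the reference units containing it as an exact substring.

    Multi-hit reads are split fractionally and equally among their hits;
    reads matching nothing count toward total_input_reads only.
    """
    counts = {unit: 0.0 for unit in reference}
    for read in reads:
        hits = [u for u, seq in reference.items() if read in seq]
        if hits:
            w = 1.0 / len(hits)
            for u in hits:
                counts[u] += w
    table = pd.DataFrame(
        {
            "Length": [len(reference[u]) for u in counts],
            "EffectiveLength": [float(len(reference[u])) for u in counts],
            "TPM": 0.0,
            "NumReads": list(counts.values()),
        },
        index=pd.Index(list(counts), name="Name"),
    )
    total = float(len(reads))
    assigned = table["NumReads"].sum()
    if total > 0:
        table["TPM"] = table["NumReads"] / max(assigned, 1e-12) * 1e6
    return QuantTable(sample_id=sample_id, table=table, total_input_reads=total)


def simulate_reads(
    reference: Mapping[str, str],
    weights: Mapping[str, float],
    n_reads: int,
    read_length: int,
    rng: np.random.Generator,
) -> list[str]:
    """Draw reads as verbatim substrings of reference units, unit chosen by weight."""
    units = [u for u in reference if weights.get(u, 0.0) > 0 and len(reference[u]) >= read_length]
    if not units:
        raise ValueError("no reference unit long enough to draw reads from")
    w = np.array([weights[u] for u in units], dtype=float)
    w /= w.sum()
    choices = rng.choice(len(units), size=n_reads, p=w)
    reads = []
    for c in choices:
        seq = reference[units[c]]
        start = int(rng.integers(0, len(seq) - read_length + 1))
        reads.append(seq[start : start + read_length])
    return reads


# ---------------------------------------------------------------------------
# count cohorts


def simulate_counts(
    catalog: FeatureCatalog, cfg: SimulationConfig
) -> tuple["object", pd.DataFrame, pd.DataFrame]:
    """NB count cohort with planted condition effects and covariates.

    Per feature i and sample j the NB mean is

        mu_ij = s_j * q_i * 2^(lfc_i * case_j) * exp(sum_k c_ik x_kj)

    with s_j log-normal library factors, q_i log-normal base abundances,
    lfc_i the planted log2 fold change (0 unless listed in cfg.planted_up)
    and c_ik per-feature covariate coefficients (sd = cfg.covariate_sd) on
    standardized covariates.  Counts are Gamma-Poisson draws with dispersion
    cfg.dispersion (variance mu + alpha mu^2).

    Returns (CountMatrix raw, metadata, truth table with per-feature lfc).
    """
    from .quantify import CountMatrix

    rng = cfg.rng(stage=2)
    feats = catalog.feature_ids
    planted = dict(cfg.planted_up)
    unknown = set(planted) - set(feats)
    if unknown:
        raise ValueError(f"planted features absent from catalog: {sorted(unknown)}")
    n = cfg.n_healthy + cfg.n_case
    samples = [f"S{j:03d}" for j in range(n)]
    condition = np.array(["healthy"] * cfg.n_healthy + ["case"] * cfg.n_case)

    metadata = pd.DataFrame(
        {
            "condition": condition,
            "age": np.round(rng.normal(60, 10, n)).clip(30, 90),
            "gender": rng.choice(["F", "M"], size=n),
            "input_volume": np.round(rng.normal(1.0, 0.2, n).clip(0.4, 2.0), 2),
            "stage": [
                "NA" if c == "healthy" else rng.choice(["I", "II", "III", "IV"])
                for c in condition
            ],
        },
        index=pd.Index(samples, name="sample_id"),
    )

    q = np.exp(rng.normal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, len(feats)))
    s = np.exp(rng.normal(0.0, cfg.library_log_sd, n))
    lfc = np.array([planted.get(f, 0.0) for f in feats])
    case = (condition == "case").astype(float)

    log_mu = (
        np.log(q)[:, None]
        + np.log(s)[None, :]
        + lfc[:, None] * case[None, :] * math.log(2.0)
    )
    if cfg.covariate_sd > 0:
        age_z = (metadata["age"] - metadata["age"].mean()) / metadata["age"].std(ddof=1)
        vol_z = (
            metadata["input_volume"] - metadata["input_volume"].mean()
        ) / metadata["input_volume"].std(ddof=1)
        gender = (metadata["gender"] == "M").astype(float) - 0.5
        for cov in (age_z.to_numpy(), vol_z.to_numpy(), gender.to_numpy()):
            c = rng.normal(0.0, cfg.covariate_sd, len(feats))
            log_mu += c[:, None] * cov[None, :]

    mu = np.exp(log_mu)
    if cfg.dispersion > 0:
        shape = 1.0 / cfg.dispersion
        lam = rng.gamma(shape, mu / shape)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(float)

    matrix = CountMatrix(
        pd.DataFrame(counts, index=pd.Index(feats, name="feature_id"), columns=samples),
        state="raw",
    )
    truth = pd.DataFrame({"log2fc": lfc, "base_mean": q}, index=pd.Index(feats, name="feature_id"))
    return matrix, metadata, truth


# ---------------------------------------------------------------------------
# fragments


def simulate_fragments(
    cfg: SimulationConfig,
    units: Sequence[CatalogUnit] | None = None,
    unit_groups: Mapping[str, str] | None = None,
) -> list[AlignedFragment]:
    """Long-read fragments with per-group mixture template lengths.

    Each fragment picks a source unit of its group, draws a template length
    from the group's Gaussian mixture (truncated > 0), and is placed inside
    the unit's interval (clipped to the unit when longer).  If no units are
    supplied, synthetic intervals are fabricated per group.
    """
    rng = cfg.rng(stage=3)
    frags: list[AlignedFragment] = []
    by_group: dict[str, list[CatalogUnit]] = {}
    if units is not None:
        groups = dict(unit_groups or {})
        for u in units:
            by_group.setdefault(groups.get(u.unit_id, "unknown"), []).append(u)
    read_no = 0
    for group, mixture in cfg.fragment_specs.items():
        pool = by_group.get(group)
        if pool is None:
            typical = max(int(max(m for _, m, _ in mixture)), 100)
            pool = [
                CatalogUnit(f"{group}_unit{k}", "chrSim", 10_000 * (k + 1), 10_000 * (k + 1) + typical)
                for k in range(5)
            ]
        weights = np.array([w for w, _, _ in mixture], dtype=float)
        weights /= weights.sum()
        for _ in range(cfg.fragments_per_group):
            w, m, sd = mixture[int(rng.choice(len(mixture), p=weights))]
            tlen = 0
            while tlen <= 0:
                tlen = int(round(rng.normal(m, sd)))
            u = pool[int(rng.integers(len(pool)))]
            span = min(tlen, u.end - u.start)
            offset = int(rng.integers(0, u.end - u.start - span + 1))
            frags.append(
                AlignedFragment(
                    read_id=f"frag{read_no:06d}",
                    chrom=u.chrom,
                    start=u.start + offset,
                    end=u.start + offset + span,
                    template_length=tlen,
                    candidate_annotations=[(u.unit_id, u.end - u.start, group)],
                )
            )
            read_no += 1
    return frags


def write_fragments_tsv(frags: Iterable[AlignedFragment], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tchrom\tstart\tend\ttemplate_length\n")
        for f in frags:
            fh.write(f"{f.read_id}\t{f.chrom}\t{f.start}\t{f.end}\t{f.template_length}\n")


def write_metadata(metadata: pd.DataFrame, path: Union[str, Path]) -> None:
    metadata.to_csv(path, sep="\t")


def write_quant_table(qt: QuantTable, path: Union[str, Path]) -> None:
    out = qt.table.reset_index().rename(columns={"index": "Name"})
    out.to_csv(path, sep="\t", index=False)
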