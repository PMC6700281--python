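"""Seeded generators for every input the pipeline consumes.

The generator emulates an HD GWAS cohort at the statistical structure the
analysis assumes: disease alleles of 40-55 CAG with a canonical /
CAA-loss / CAACAG-duplication structure mix, age at motor onset equal to
the model expectation for the *true* CAG plus additive modifier-SNP
effects (years per minor allele) and Gaussian residual noise, estimated
CAG distorted by the fragment-assay model per structure class, SNP
genotypes drawn under Hardy-Weinberg equilibrium, 2x300 bp amplicon read
pairs with independent per-base substitution errors, and GeneMapper-style
fragment-trace peak tables whose right-of-main expansion tail carries a
per-subject propensity that increases with CAG and optionally with the
dosage of a designated modifier allele.

Every generator draws from an independent child stream of a single seed,
so outputs are byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import onset_phenotype, repeat_model
from .read_profiler import ReadPair
from .repeat_model import RepeatStructure, StructureClass, make_structure

__all__ = [
    "SnpSpec",
    "TraceConfig",
    "ReadConfig",
    "SimConfig",
    "AlleleSim",
    "CohortSim",
    "simulate_alleles",
    "simulate_read_pairs",
    "simulate_reads_fastq",
    "simulate_trace",
    "simulate_trace_cohort",
    "simulate_cohort",
]

#: Fixed synthetic primer-side / downstream context (no CAG anchor, in frame).
REGION_PREFIX = "GCCTTCGAGTCCCTCAAGTCCTTC"
REGION_SUFFIX = "GCCGCCTCCTCAGCTTCCTCAGCCGCCGCC"


@dataclass(frozen=True)
class SnpSpec:
    """A modifier SNP: allele frequency and additive effect on onset."""

    id: str
    maf: float
    effect: float            # years per minor allele (negative = hastening)

    @property
    def direction(self) -> str:
        return "hastening" if self.effect < 0 else "delaying"


# Default modifier panel mirroring reported locus tag SNPs (MAF, years/allele).
DEFAULT_SNPS: tuple[SnpSpec, ...] = (
    SnpSpec("rs701383", 0.257, -0.8),
    SnpSpec("rs3791767", 0.207, -0.8),
    SnpSpec("rs35811129", 0.275, 1.3),
    SnpSpec("rs150393409", 0.014, -5.2),
    SnpSpec("rs274883", 0.167, 0.9),
)


@dataclass(frozen=True)
class ReadConfig:
    read_length: int = 300
    coverage: int = 100              # pairs per allele
    base_error: float = 0.005


@dataclass(frozen=True)
class TraceConfig:
    main_height: float = 10000.0     # RFU
    n_stutter: int = 4               # left-of-main stutter peaks
    stutter_decay: float = 0.5
    n_expansion_peaks: int = 3       # right-of-main expansion peaks
    expansion_decay: float = 0.5     # geometric split of the expansion mass
    mean_base: float = 0.05          # mean propensity at 40 CAG
    mean_slope: float = 0.012        # propensity increase per CAG above 40
    concentration: float = 20.0      # Beta concentration of the propensity
    coupling_snp: Optional[str] = "rs701383"
    coupling: float = 0.25           # relative propensity increase per allele
    size_intercept: float = 87.0     # bp at zero CAG
    bp_per_cag: float = 3.0
    size_jitter: float = 0.3         # uniform bp jitter on peak sizes
    plate_size: int = 96


@dataclass(frozen=True)
class SimConfig:
    """Study-condition defaults for the synthetic cohort."""

    seed: int
    n_subjects: int = 9064
    cag_range: tuple[int, int] = (40, 55)
    cag_decay: float = 0.35          # P(L) ~ exp(-decay*(L-40))
    normal_cag_range: tuple[int, int] = (15, 25)
    structure_mix: tuple[tuple[str, float], ...] = (
        ("canonical", 0.9855),
        ("caa_loss", 0.0032),
        ("caacag_dup", 0.0113),
        ("other", 0.0),
    )
    misprime_prob: float = 0.5
    residual_sd: float = 7.0         # years
    snps: tuple[SnpSpec, ...] = DEFAULT_SNPS
    # A rare SNP tagging CAA-loss chromosomes (carriers get one minor allele),
    # reproducing the mis-estimation artifact; effect 0 = no biological effect.
    caa_loss_tag_snp: Optional[str] = "rs764154313"
    reads: ReadConfig = field(default_factory=ReadConfig)
    trace: TraceConfig = field(default_factory=TraceConfig)

    def __post_init__(self) -> None:
        total = sum(p for _, p in self.structure_mix)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("structure_mix proportions must sum to 1")
        for _, p in self.structure_mix:
            if not (0 <= p <= 1):
                raise ValueError("proportions must lie in [0, 1]")

    def streams(self) -> dict[str, np.random.Generator]:
        names = ["alleles", "reads", "trace", "cohort"]
        children = np.random.SeedSequence(self.seed).spawn(len(names))
        return {n: np.random.default_rng(c) for n, c in zip(names, children)}


@dataclass(frozen=True)
class AlleleSim:
    """True per-subject allele pair."""

    subject: str
    disease: RepeatStructure
    normal: RepeatStructure
    cls: StructureClass
    misprime: bool

    @property
    def true_cag(self) -> int:
        return repeat_model.uninterrupted_cag_length(self.disease)


def _cag_probs(config: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = config.cag_range
    lengths = np.arange(lo, hi + 1)
    w = np.exp(-config.cag_decay * (lengths - lo))
    return lengths, w / w.sum()


def simulate_alleles(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> list[AlleleSim]:
    """Draw per-subject disease/normal repeat structures."""
    rng = rng if rng is not None else config.streams()["alleles"]
    lengths, probs = _cag_probs(config)
    classes = [StructureClass(name) for name, _ in config.structure_mix]
    mix = np.array([p for _, p in config.structure_mix])
    n = config.n_subjects
    dis_cag = rng.choice(lengths, size=n, p=probs)
    cls_idx = rng.choice(len(classes), size=n, p=mix)
    norm_cag = rng.integers(
        config.normal_cag_range[0], config.normal_cag_range[1] + 1, size=n
    )
    misprime = rng.random(n) < config.misprime_prob
    out = []
    for i in range(n):
        cls = classes[cls_idx[i]]
        out.append(
            AlleleSim(
                subject=f"S{i:05d}",
                disease=make_structure(cls, int(dis_cag[i])),
                normal=make_structure(StructureClass.CANONICAL, int(norm_cag[i])),
                cls=cls,
                misprime=bool(misprime[i]),
            )
        )
    return out


def region_sequence(structure: RepeatStructure) -> str:
    """Full amplicon sequence for a repeat structure."""
    return REGION_PREFIX + structure.to_dna() + repeat_model.TERMINATOR + REGION_SUFFIX


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _mutate(seq: str, error: float, rng: np.random.Generator) -> str:
    if error <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < error)[0]
    if hits.size:
        # substitute with one of the three other bases
        for i in hits:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


def simulate_read_pairs(
    alleles: Sequence[RepeatStructure],
    config: SimConfig,
    rng: np.random.Generator,
    sample: str = "S",
) -> tuple[list[ReadPair], list[bool]]:
    """2x300 bp sense/antisense pairs with independent per-base errors.

    Returns the pairs plus a per-pair ``truncated`` flag set when the
    amplicon exceeds the read length (pairs are still emitted).
    """
    rc = config.reads
    pairs: list[ReadPair] = []
    truncated: list[bool] = []
    k = 0
    for ai, structure in enumerate(alleles):
        amplicon = region_sequence(structure)
        trunc = len(amplicon) > rc.read_length
        fwd_t = amplicon[: rc.read_length]
        rev_t = _revcomp(amplicon)[: rc.read_length]
        for _ in range(rc.coverage):
            pairs.append(
                ReadPair(
                    id=f"{sample}:a{ai}:p{k}",
                    forward=_mutate(fwd_t, rc.base_error, rng),
                    mate=_mutate(rev_t, rc.base_error, rng),
                )
            )
            truncated.append(trunc)
            k += 1
    return pairs, truncated


def simulate_reads_fastq(
    alleles: Sequence[RepeatStructure],
    config: SimConfig,
    rng: np.random.Generator,
    fastq1,
    fastq2,
    sample: str = "S",
) -> None:
    """Write simulated pairs as two FASTQ files (uniform Q30 qualities)."""
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    pairs, _ = simulate_read_pairs(alleles, config, rng, sample=sample)

    def rec(rid: str, seq: str) -> SeqRecord:
        r = SeqRecord(Seq(seq), id=rid, description="")
        r.letter_annotations["phred_quality"] = [30] * len(seq)
        return r

    SeqIO.write([rec(p.id + "/1", p.forward) for p in pairs], fastq1, "fastq")
    SeqIO.write([rec(p.id + "/2", p.mate) for p in pairs], fastq2, "fastq")


def expansion_propensity_mean(
    cag: int, dosage: float, trace: TraceConfig
) -> float:
    """Mean expansion propensity: increases with CAG and modifier dosage."""
    base = trace.mean_base + trace.mean_slope * (cag - 40)
    return float(np.clip(base * (1.0 + trace.coupling * dosage), 1e-3, 0.8))


def simulate_trace(
    sample: str,
    main_cag: int,
    propensity: float,
    plate: str,
    trace: TraceConfig,
    rng: np.random.Generator,
) -> list[dict]:
    """Peak rows for one sample: main peak, left stutter, right expansions.

    The right-of-main expansion mass totals ``propensity`` of the main-peak
    height, split geometrically over ``n_expansion_peaks`` peaks.
    """

    def size_of(cag: int) -> float:
        jitter = rng.uniform(-trace.size_jitter, trace.size_jitter)
        return trace.size_intercept + trace.bp_per_cag * cag + jitter

    def row(cag: int, height: float) -> dict:
        size = size_of(cag)
        return {
            "sample": sample,
            "plate": plate,
            "called_cag": main_cag,
            "size_bp": round(size, 2),
            "height_rfu": round(height, 1),
            "area": round(height * 3.0, 1),
            "scan": int(size * 10),
        }

    rows = [row(main_cag, trace.main_height)]
    for k in range(1, trace.n_stutter + 1):
        if main_cag - k < 1:
            break
        rows.append(row(main_cag - k, trace.main_height * trace.stutter_decay ** k))
    if propensity > 0:
        w = trace.expansion_decay ** np.arange(trace.n_expansion_peaks)
        w = w / w.sum()
        for k, wk in enumerate(w, start=1):
            rows.append(row(main_cag + k, trace.main_height * propensity * wk))
    return rows


def simulate_trace_cohort(
    cohort: pd.DataFrame,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
    dosages: Optional[pd.DataFrame] = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Peak tables for a whole cohort; returns (peaks, true propensities).

    Per-subject propensity ~ Beta with mean increasing in CAG (and in the
    coupling SNP dosage when ``dosages`` carries the configured SNP).
    """
    rng = rng if rng is not None else config.streams()["trace"]
    tc = config.trace
    rows: list[dict] = []
    propensities = {}
    for i, rec in enumerate(cohort.itertuples(index=False)):
        cag = int(rec.est_cag)
        dosage = 0.0
        if (
            dosages is not None
            and tc.coupling_snp is not None
            and tc.coupling_snp in dosages.columns
        ):
            dosage = float(dosages.loc[rec.id, tc.coupling_snp])
        mean = expansion_propensity_mean(cag, dosage, tc)
        a = mean * tc.concentration
        b = (1 - mean) * tc.concentration
        propensity = float(rng.beta(a, b))
        propensities[rec.id] = propensity
        plate = f"P{(i // tc.plate_size):03d}"
        rows.extend(simulate_trace(rec.id, cag, propensity, plate, tc, rng))
    peaks = pd.DataFrame(rows, columns=[
        "sample", "plate", "called_cag", "size_bp", "height_rfu", "area", "scan"
    ])
    return peaks, pd.Series(propensities, name="propensity")


@dataclass
class CohortSim:
    """Bundle of generated cohort inputs plus the generating truth."""

    cohort: pd.DataFrame        # id, sex, onset_years, est_cag, true_cag, cls, misprime
    dosages: pd.DataFrame       # subjects x SNPs, minor allele counts
    alleles: list[AlleleSim]
    truth: dict

    def truth_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=1, default=str)


def simulate_cohort(
    config: SimConfig, model: Optional[onset_phenotype.OnsetModel] = None
) -> CohortSim:
    """Generate the full cohort: alleles, genotypes, onsets, estimated CAG.

    onset = expected(true CAG) + sum(dosage * effect) + Normal(0, sd);
    estimated CAG is the fragment-assay reading of the true structure.
    """
    streams = config.streams()
    model = model if model is not None else onset_phenotype.default_model()
    alleles = simulate_alleles(config, streams["alleles"])
    rng = streams["cohort"]
    n = config.n_subjects

    dosage_cols = {}
    for snp in config.snps:
        dosage_cols[snp.id] = rng.binomial(2, snp.maf, size=n)
    caa_carrier = np.array([a.cls is StructureClass.CAA_LOSS for a in alleles])
    if config.caa_loss_tag_snp is not None:
        tag = rng.binomial(2, 0.002, size=n)
        tag[caa_carrier] = np.maximum(tag[caa_carrier], 1)
        dosage_cols[config.caa_loss_tag_snp] = tag
    ids = [a.subject for a in alleles]
    dosages = pd.DataFrame(dosage_cols, index=pd.Index(ids, name="id"))

    sex = np.where(rng.random(n) < 0.5, "F", "M")
    true_cag = np.array([a.true_cag for a in alleles])
    expected = np.array([model.expected(c) for c in true_cag])
    effects = np.zeros(n)
    for snp in config.snps:
        effects += dosages[snp.id].to_numpy() * snp.effect
    noise = rng.normal(0.0, config.residual_sd, size=n)
    onset = np.maximum(expected + effects + noise, 2.0)

    est_cag = np.array(
        [
            repeat_model.fragment_assay_estimate(a.true_cag, a.cls, a.misprime)
            for a in alleles
        ]
    )
    cohort = pd.DataFrame(
        {
            "id": ids,
            "sex": sex,
            "onset_years": np.round(onset, 2),
            "est_cag": est_cag,
            "true_cag": true_cag,
            "cls": [a.cls.value for a in alleles],
            "misprime": [a.misprime for a in alleles],
        }
    )
    truth = {
        "seed": config.seed,
        "n_subjects": n,
        "model": {"form": model.form, "coef": list(model.coef)},
        "residual_sd": config.residual_sd,
        "snps": [dataclasses.asdict(s) for s in config.snps],
        "structure_mix": dict(config.structure_mix),
        "n_caa_loss": int(caa_carrier.sum()),
        "n_caacag_dup": int(
            sum(a.cls is StructureClass.CAACAG_DUP for a in alleles)
        ),
    }
    return CohortSim(cohort=cohort, dosages=dosages, alleles=alleles, truth=truth)


def config_from_yaml(path) -> SimConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if "snps" in raw:
        raw["snps"] = tuple(SnpSpec(**s) for s in raw["snps"])
    if "reads" in raw:
        raw["reads"] = ReadConfig(**raw["reads"])
    if "trace" in raw:
        raw["trace"] = TraceConfig(**raw["trace"])
    for key in ("cag_range", "normal_cag_range"):
        if key in raw:
            raw[key] = tuple(raw[key])
    if "structure_mix" in raw:
        raw["structure_mix"] = tuple((k, v) for k, v in raw["structure_mix"].items())
    return SimConfig(**raw)
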