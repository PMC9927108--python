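"""Synthetic multikingdom cohort generator with recorded ground truth.

Emulates a two-group case-control gut-metagenome study (44 patients vs 46
controls by default): prokaryote reference genomes carrying CRISPR arrays,
viral contigs with near-duplicate variants and planted protospacers,
predictor-verdict tables for viral triage, and per-sample abundance tables
for bacteria, fungi, vOTUs and pathways with planted differential features.
Every planted fact (differential features, vOTU families and hosts,
duplicate identities) is recorded in a :class:`PlantedTruth` so downstream
stages can be tested for exact recovery without any external data.

Baseline abundances are log-normal(0, dispersion) per feature and sample;
planted features are multiplied by ``effect_size`` in their enriched group.
Directions are split evenly between the two groups so that closure
(per-sample renormalization) does not shift the null features. Duplicate
contigs are produced by prefix truncation (controls coverage) and uniform
random substitutions without indels (controls identity exactly).
"""

from __future__ import annotations

import dataclasses
import json
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .profiling import RANKS

__all__ = [
    "TruthConfig",
    "PlantedTruth",
    "ReferenceSet",
    "Cohort",
    "Dataset",
    "generate_genomes",
    "generate_viral_contigs",
    "generate_decoy_contigs",
    "generate_predictor_verdicts",
    "generate_cohort",
    "generate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
VIRAL_FAMILIES = (
    "Siphoviridae",
    "Myoviridae",
    "Podoviridae",
    "Microviridae",
    "Quimbyviridae",
    "Herelleviridae",
)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, positions: np.ndarray) -> str:
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    for p in positions:
        old = arr[p]
        choices = _BASES[_BASES != old]
        arr[p] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# configuration and truth


@dataclasses.dataclass
class TruthConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the target study design: 44 patients ("OA") vs 46
    controls ("HC"), age- and BMI-matched covariates, log-normal baseline
    abundances with log-scale SD ``dispersion``, and 8-fold planted effects
    on a fifth of the features of each kingdom. Feature counts are a
    desk-scale reduction of the thousands profiled in a real cohort.
    """

    n_oa: int = 44
    n_hc: int = 46
    n_bact_species: int = 120
    n_fungal_species: int = 30
    n_votus: int = 40
    frac_differential: float = 0.2
    effect_size: float = 8.0
    dispersion: float = 1.5
    # covariate model: age in years, BMI in kg/m^2, sex as Bernoulli(p_female)
    age_mean: float = 60.0
    age_sd: float = 8.0
    bmi_mean: float = 24.0
    bmi_sd: float = 3.0
    p_female: float = 0.5
    # optional knobs (both off by default)
    confound_strength: float = 0.0  # covariate-driven log-abundance loading
    host_coupling: bool = False  # vOTU abundance tracks a bacterial species
    n_pathways: int = 50
    n_kos: int = 25
    n_diff_kos: int = 6
    genome_length: int = 20_000
    contig_length: int = 12_000
    genes_per_contig: int = 8
    frac_with_protospacer: float = 1.0
    duplicate_ani_grid: tuple[tuple[float, float], ...] = ((0.99, 1.0), (0.97, 0.9))
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_oa, self.n_hc, self.n_bact_species, self.n_fungal_species,
            self.n_votus, self.n_pathways, self.n_kos,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.frac_differential <= 1.0:
            raise ValueError("frac_differential must lie in [0, 1]")
        if self.effect_size < 1.0:
            raise ValueError("effect_size must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")


@dataclasses.dataclass
class PlantedTruth:
    """Ground truth recorded while generating a synthetic dataset."""

    differential_features: dict[str, str] = dataclasses.field(default_factory=dict)
    votu_family: dict[str, str] = dataclasses.field(default_factory=dict)
    votu_host: dict[str, str] = dataclasses.field(default_factory=dict)
    duplicate_pairs: list[tuple[str, str, float, float]] = dataclasses.field(
        default_factory=list
    )
    viral_ids: set[str] = dataclasses.field(default_factory=set)
    decoy_ids: set[str] = dataclasses.field(default_factory=set)
    base_votus: list[str] = dataclasses.field(default_factory=list)
    differential_kos: dict[str, str] = dataclasses.field(default_factory=dict)
    confounded_features: list[str] = dataclasses.field(default_factory=list)
    votu_tracking: dict[str, str] = dataclasses.field(default_factory=dict)
    crispr_arrays: list[dict] = dataclasses.field(default_factory=list)

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["viral_ids"] = sorted(self.viral_ids)
        d["decoy_ids"] = sorted(self.decoy_ids)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PlantedTruth":
        d = json.loads(text)
        d["viral_ids"] = set(d["viral_ids"])
        d["decoy_ids"] = set(d["decoy_ids"])
        d["duplicate_pairs"] = [tuple(t) for t in d["duplicate_pairs"]]
        return cls(**d)


# ---------------------------------------------------------------------------
# reference genomes with planted CRISPR arrays


@dataclasses.dataclass
class ReferenceSet:
    """Synthetic prokaryote reference genomes with genus labels."""

    genomes: dict[str, str]
    genus: dict[str, str]
    taxonomy: pd.DataFrame
    arrays: list[dict]  # genome_id, start, repeat, spacers


def _species_taxonomy(ids: Sequence[str], domain: str) -> pd.DataFrame:
    """Nested synthetic taxonomy: 4 species/genus, 8/family, ... 64/phylum."""
    prefix = domain[:4]
    rows = []
    for i, sid in enumerate(ids):
        rows.append(
            {
                "domain": domain,
                "phylum": f"{prefix}_p{i // 64 + 1:02d}",
                "class": f"{prefix}_c{i // 32 + 1:02d}",
                "order": f"{prefix}_o{i // 16 + 1:02d}",
                "family": f"{prefix}_f{i // 8 + 1:02d}",
                "genus": f"{prefix}_g{i // 4 + 1:02d}",
                "species": sid,
            }
        )
    return pd.DataFrame(rows, index=pd.Index(ids, name="feature"), columns=RANKS)


def _plant_array(
    rng: np.random.Generator, genome: np.ndarray, start: int
) -> tuple[np.ndarray, dict]:
    """Write a CRISPR array (3 exact repeat copies, unique spacers) into
    ``genome`` (byte array) at ``start``; returns the truth record."""
    rep_len = int(rng.integers(25, 41))
    repeat = _random_seq(rng, rep_len)
    spacers = []
    while len(spacers) < 2:
        sp = _random_seq(rng, int(rng.integers(28, 41)))
        if sp not in spacers:
            spacers.append(sp)
    block = repeat + spacers[0] + repeat + spacers[1] + repeat
    arr = np.frombuffer(block.encode(), dtype="S1")
    genome[start : start + len(arr)] = arr
    # guard the flanks so detection is exact: the genome base before the
    # first copy must differ from the last base of EVERY spacer (else a
    # shifted seed can form a partial chain that shadows the true array),
    # and symmetrically after the last copy
    left = {s[-1].encode() for s in spacers}
    if start > 0:
        genome[start - 1] = next(b for b in _BASES if b not in left)
    right = {s[0].encode() for s in spacers}
    tail = start + len(arr)
    if tail < len(genome):
        genome[tail] = next(b for b in _BASES if b not in right)
    return genome, {
        "genome_id": "",
        "start": start,
        "repeat": repeat,
        "spacers": spacers,
    }


def generate_genomes(
    n_species: int,
    length: int = 20_000,
    n_with_crispr: int | None = None,
    seed: int = 0,
) -> ReferenceSet:
    """Generate prokaryote reference genomes with genus labels; the first
    ``n_with_crispr`` genomes carry one planted CRISPR array each."""
    if n_species <= 0 or length < 5000:
        raise ValueError("n_species must be positive and length >= 5000")
    if n_with_crispr is None:
        n_with_crispr = n_species
    if not 0 <= n_with_crispr <= n_species:
        raise ValueError("n_with_crispr must lie in [0, n_species]")
    rng = np.random.default_rng(seed)
    ids = [f"bact_{i + 1:04d}" for i in range(n_species)]
    taxonomy = _species_taxonomy(ids, "Bacteria")
    genus = taxonomy["genus"].to_dict()
    genomes: dict[str, str] = {}
    arrays: list[dict] = []
    for i, sid in enumerate(ids):
        g = np.frombuffer(_random_seq(rng, length).encode(), dtype="S1").copy()
        if i < n_with_crispr:
            start = int(rng.integers(200, length - 400))
            g, rec = _plant_array(rng, g, start)
            rec["genome_id"] = sid
            arrays.append(rec)
        genomes[sid] = g.tobytes().decode()
    return ReferenceSet(genomes=genomes, genus=genus, taxonomy=taxonomy, arrays=arrays)


# ---------------------------------------------------------------------------
# viral contigs


def generate_viral_contigs(
    hosts: ReferenceSet | None,
    n_votus: int,
    genes_per_contig: int = 8,
    frac_with_protospacer: float = 1.0,
    duplicate_ani_grid: Sequence[tuple[float, float]] = ((0.99, 1.0), (0.97, 0.9)),
    base_length: int = 12_000,
    frac_family_genes: float = 0.5,
    seed: int = 0,
    truth: PlantedTruth | None = None,
) -> tuple[dict[str, str], pd.DataFrame, PlantedTruth]:
    """Generate base viral contigs plus near-duplicate variants.

    Each of the ``n_votus`` base contigs founds one true vOTU and receives
    one derived duplicate per ``(identity, coverage)`` grid entry: a prefix
    of relative length ``coverage`` with exactly ``round((1-identity)*len)``
    substitutions. The gene table labels ``frac_family_genes`` of each
    contig's genes with the vOTU's true family. Protospacer-bearing base
    contigs contain an exact copy of a CRISPR spacer from their true host
    genus.
    """
    if n_votus <= 0:
        raise ValueError("n_votus must be positive")
    if base_length < 5000:
        raise ValueError("base_length must be >= 5000")
    for ident, cov in duplicate_ani_grid:
        if not (0 <= ident <= 1 and 0 < cov <= 1):
            raise ValueError(f"grid entry ({ident}, {cov}) out of [0, 1]")
    if frac_with_protospacer > 0 and (hosts is None or not hosts.arrays):
        raise ValueError("protospacers requested but no host CRISPR arrays available")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else PlantedTruth()

    contigs: dict[str, str] = {}
    gene_rows: list[dict] = []
    n_spacered = round(frac_with_protospacer * n_votus)
    spacer_sources = hosts.arrays if hosts is not None else []
    for v in range(n_votus):
        vid = f"viral_{v + 1:04d}"
        seq = _random_seq(rng, base_length)
        truth.base_votus.append(vid)
        truth.votu_family[vid] = VIRAL_FAMILIES[v % len(VIRAL_FAMILIES)]
        if v < n_spacered:
            arr = spacer_sources[v % len(spacer_sources)]
            spacer = arr["spacers"][v % len(arr["spacers"])]
            pos = int(rng.integers(0, base_length - len(spacer)))
            seq = seq[:pos] + spacer + seq[pos + len(spacer) :]
            truth.votu_host[vid] = hosts.genus[arr["genome_id"]]
        contigs[vid] = seq
        truth.viral_ids.add(vid)
        for d, (ident, cov) in enumerate(duplicate_ani_grid):
            dup_len = int(round(cov * base_length))
            n_mut = int(round((1.0 - ident) * dup_len))
            dup = contigs[vid][:dup_len]
            if n_mut:
                pos_mut = rng.choice(dup_len, size=n_mut, replace=False)
                dup = _mutate(rng, dup, pos_mut)
            did = f"{vid}_d{d + 1:02d}"
            contigs[did] = dup
            truth.viral_ids.add(did)
            truth.duplicate_pairs.append(
                (vid, did, 1.0 - n_mut / dup_len, dup_len / base_length)
            )

    n_fam = int(np.ceil(frac_family_genes * genes_per_contig))
    for cid, seq in contigs.items():
        base_id = cid.split("_d")[0]
        family = truth.votu_family[base_id]
        step = len(seq) // genes_per_contig
        for j in range(genes_per_contig):
            gene_rows.append(
                {
                    "contig_id": cid,
                    "gene_id": f"{cid}_g{j + 1:02d}",
                    "start": j * step,
                    "end": min((j + 1) * step, len(seq)) - 1,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    "family": family if j < n_fam else "",
                    "ko": f"K{int(rng.integers(1, 100)):05d}" if rng.random() < 0.3 else "",
                }
            )
    genes = pd.DataFrame(gene_rows)
    return contigs, genes, truth


def generate_decoy_contigs(
    hosts: ReferenceSet,
    n: int,
    length: int = 8000,
    seed: int = 0,
    truth: PlantedTruth | None = None,
) -> tuple[dict[str, str], PlantedTruth]:
    """Cut non-viral decoy contigs out of the host genomes (negatives for
    the predictor-verdict model)."""
    if n < 0 or length < 1000:
        raise ValueError("need n >= 0 and length >= 1000")
    rng = np.random.default_rng(seed)
    truth = truth if truth is not None else PlantedTruth()
    ids = sorted(hosts.genomes)
    decoys: dict[str, str] = {}
    for i in range(n):
        gid = ids[int(rng.integers(0, len(ids)))]
        g = hosts.genomes[gid]
        L = min(length, len(g))
        start = int(rng.integers(0, len(g) - L + 1))
        did = f"decoy_{i + 1:04d}"
        decoys[did] = g[start : start + L]
        truth.decoy_ids.add(did)
    return decoys, truth


# ---------------------------------------------------------------------------
# predictor verdicts


def _as_triple(x) -> tuple[float, float, float]:
    if np.isscalar(x):
        return (float(x),) * 3
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise ValueError("per-tool rates need exactly 3 values")
    return t


def generate_predictor_verdicts(
    contigs: Mapping[str, str],
    truth: PlantedTruth,
    sens: float | Sequence[float] = 1.0,
    spec: float | Sequence[float] = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Emulated verdicts of the three virus predictors for every contig.

    ``sens``/``spec`` are per-tool sensitivities/specificities (scalar =
    shared by the gene-count, binary-call, and score-based predictors; the
    three tools err independently). With ``sens = spec = 1`` the verdicts
    reproduce the planted truth exactly. True viral contigs draw a
    medium-or-better quality tier; decoys draw Low/Not-determined.
    """
    s_checkv, s_vib, s_dvf = _as_triple(sens)
    p_checkv, p_vib, p_dvf = _as_triple(spec)
    for r in (s_checkv, s_vib, s_dvf, p_checkv, p_vib, p_dvf):
        if not 0.0 <= r <= 1.0:
            raise ValueError("sensitivities/specificities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for cid in contigs:
        viral = cid in truth.viral_ids
        pos = [
            rng.random() < (s if viral else 1.0 - p)
            for s, p in ((s_checkv, p_checkv), (s_vib, p_vib), (s_dvf, p_dvf))
        ]
        if pos[0]:
            vg, mg = int(rng.integers(3, 11)), int(rng.integers(0, 3))
        else:
            vg, mg = int(rng.integers(0, 3)), int(rng.integers(3, 9))
        if pos[2]:
            score, pval = rng.uniform(0.905, 1.0), rng.uniform(0.0, 0.009)
        else:
            score, pval = rng.uniform(0.0, 0.9), rng.uniform(0.02, 1.0)
        quality = (
            rng.choice(["Complete", "High", "Medium"], p=[0.05, 0.25, 0.70])
            if viral
            else rng.choice(["Low", "Not-determined"], p=[0.7, 0.3])
        )
        rows.append(
            {
                "contig_id": cid,
                "length": len(contigs[cid]),
                "checkv_viral_genes": vg,
                "checkv_microbial_genes": mg,
                "vibrant_call": bool(pos[1]),
                "dvf_score": float(score),
                "dvf_p": float(pval),
                "checkv_quality": str(quality),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort abundance tables


@dataclasses.dataclass
class Cohort:
    """Per-sample tables of a synthetic case-control cohort."""

    bacteria: pd.DataFrame  # features x samples counts
    fungi: pd.DataFrame
    votus: pd.DataFrame
    pathways: pd.DataFrame
    ko_presence: pd.DataFrame  # differential vOTUs x KOs, 0/1
    metadata: pd.DataFrame  # sample -> group, age, sex, bmi
    taxonomy_bacteria: pd.DataFrame
    taxonomy_fungi: pd.DataFrame


def _abundance_table(
    rng: np.random.Generator,
    features: Sequence[str],
    samples: Sequence[str],
    groups: pd.Series,
    config: TruthConfig,
    truth: PlantedTruth,
    n_differential: int,
) -> pd.DataFrame:
    """Log-normal baseline with planted fold-changes, directions balanced
    between the two groups."""
    n_f, n_s = len(features), len(samples)
    x = np.exp(config.dispersion * rng.standard_normal((n_f, n_s)))
    if n_differential > 0 and config.effect_size > 1.0:
        chosen = rng.choice(n_f, size=n_differential, replace=False)
        for k, fi in enumerate(sorted(chosen)):
            direction = "OA" if k % 2 == 0 else "HC"
            mask = (groups == direction).to_numpy()
            x[fi, mask] *= config.effect_size
            truth.differential_features[features[fi]] = direction
    return pd.DataFrame(x, index=pd.Index(features, name="feature"), columns=samples)


def generate_cohort(
    config: TruthConfig, truth: PlantedTruth | None = None
) -> tuple[Cohort, PlantedTruth]:
    """Generate all per-sample tables plus metadata for the cohort.

    Covariates are drawn independently of group (age- and BMI-matched
    design) unless ``config.confound_strength > 0``, which additionally
    drives a few null bacterial features by the (standardized) BMI so that
    covariate adjustment can be exercised. With ``config.host_coupling``,
    each differential vOTU's abundance tracks a same-direction differential
    bacterial species (shared latent factor with small log-normal noise).
    """
    truth = truth if truth is not None else PlantedTruth()
    rng = np.random.default_rng(config.seed + 1_000_003)
    samples = [f"OA_{i + 1:03d}" for i in range(config.n_oa)] + [
        f"HC_{i + 1:03d}" for i in range(config.n_hc)
    ]
    groups = pd.Series(
        ["OA"] * config.n_oa + ["HC"] * config.n_hc, index=samples, name="group"
    )
    age = np.round(rng.normal(config.age_mean, config.age_sd, len(samples)), 1)
    sex = (rng.random(len(samples)) < config.p_female).astype(int)
    bmi = np.round(rng.normal(config.bmi_mean, config.bmi_sd, len(samples)), 1)
    metadata = pd.DataFrame(
        {"group": groups, "age": age, "sex": sex, "bmi": bmi},
        index=pd.Index(samples, name="sample"),
    )

    bact_ids = [f"bact_{i + 1:04d}" for i in range(config.n_bact_species)]
    fung_ids = [f"fung_{i + 1:03d}" for i in range(config.n_fungal_species)]
    votu_ids = list(truth.base_votus) or [
        f"viral_{i + 1:04d}" for i in range(config.n_votus)
    ]
    pwy_ids = [f"pwy_{i + 1:03d}" for i in range(config.n_pathways)]

    n_diff = lambda n: int(round(config.frac_differential * n))
    bacteria = _abundance_table(
        rng, bact_ids, samples, groups, config, truth, n_diff(len(bact_ids))
    )
    fungi = _abundance_table(
        rng, fung_ids, samples, groups, config, truth, n_diff(len(fung_ids))
    )
    votus = _abundance_table(
        rng, votu_ids, samples, groups, config, truth, n_diff(len(votu_ids))
    )
    pathways = _abundance_table(
        rng, pwy_ids, samples, groups, config, truth, n_diff(len(pwy_ids))
    )

    if config.confound_strength > 0:
        null_bact = [b for b in bact_ids if b not in truth.differential_features]
        chosen = list(rng.choice(len(null_bact), size=4, replace=False))
        z_bmi = (bmi - bmi.mean()) / bmi.std()
        for idx in sorted(chosen):
            fid = null_bact[idx]
            bacteria.loc[fid] *= np.exp(config.confound_strength * z_bmi)
            truth.confounded_features.append(fid)

    diff_votus = [v for v in votu_ids if v in truth.differential_features]
    if config.host_coupling:
        diff_bact = [b for b in bact_ids if b in truth.differential_features]
        for v in diff_votus:
            direction = truth.differential_features[v]
            partners = [b for b in diff_bact if truth.differential_features[b] == direction]
            b = partners[len(truth.votu_tracking) % len(partners)]
            noise = np.exp(0.3 * rng.standard_normal(len(samples)))
            votus.loc[v] = bacteria.loc[b].to_numpy() * noise
            truth.votu_tracking[v] = b

    # KO presence over the differential vOTUs: planted KOs follow the vOTU
    # enrichment direction exactly; background KOs are Bernoulli(0.3)
    ko_ids = [f"K{i + 1:05d}" for i in range(config.n_kos)]
    ko = (rng.random((len(diff_votus), config.n_kos)) < 0.3).astype(int)
    ko = pd.DataFrame(ko, index=pd.Index(diff_votus, name="votu"), columns=ko_ids)
    directions = pd.Series({v: truth.differential_features[v] for v in diff_votus})
    for k in range(min(config.n_diff_kos, config.n_kos)):
        direction = "OA" if k % 2 == 0 else "HC"
        ko[ko_ids[k]] = (directions == direction).astype(int).to_numpy()
        truth.differential_kos[ko_ids[k]] = direction

    cohort = Cohort(
        bacteria=bacteria,
        fungi=fungi,
        votus=votus,
        pathways=pathways,
        ko_presence=ko,
        metadata=metadata,
        taxonomy_bacteria=_species_taxonomy(bact_ids, "Bacteria"),
        taxonomy_fungi=_species_taxonomy(fung_ids, "Fungi"),
    )
    return cohort, truth


# ---------------------------------------------------------------------------
# one-call dataset


@dataclasses.dataclass
class Dataset:
    """A complete synthetic study: references, contigs, verdicts, cohort."""

    config: TruthConfig
    references: ReferenceSet
    contigs: dict[str, str]  # viral + decoy contigs
    genes: pd.DataFrame
    verdicts: pd.DataFrame
    cohort: Cohort
    truth: PlantedTruth


def generate_dataset(
    config: TruthConfig,
    n_decoys: int = 20,
    sens: float | Sequence[float] = 1.0,
    spec: float | Sequence[float] = 1.0,
) -> Dataset:
    """Generate the full study: genomes -> viral/decoy contigs -> predictor
    verdicts -> cohort tables, with one shared :class:`PlantedTruth`."""
    refs = generate_genomes(
        config.n_bact_species,
        length=config.genome_length,
        n_with_crispr=max(2, config.n_bact_species // 2),
        seed=config.seed,
    )
    contigs, genes, truth = generate_viral_contigs(
        refs,
        config.n_votus,
        genes_per_contig=config.genes_per_contig,
        frac_with_protospacer=config.frac_with_protospacer,
        duplicate_ani_grid=config.duplicate_ani_grid,
        base_length=config.contig_length,
        seed=config.seed + 1,
    )
    decoys, truth = generate_decoy_contigs(
        refs, n_decoys, seed=config.seed + 2, truth=truth
    )
    all_contigs = {**contigs, **decoys}
    verdicts = generate_predictor_verdicts(
        all_contigs, truth, sens=sens, spec=spec, seed=config.seed + 3
    )
    cohort, truth = generate_cohort(config, truth)
    return Dataset(
        config=config,
        references=refs,
        contigs=all_contigs,
        genes=genes,
        verdicts=verdicts,
        cohort=cohort,
        truth=truth,
    )
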