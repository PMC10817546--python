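"""Synthetic AMF amplicon study generator.

Emits everything the downstream pipeline consumes, with known ground truth:
a reference database of Glomeromycota rDNA constructs (18S tail - ITS1 -
5.8S - ITS2 - 28S head) with 6-rank lineages, per-sample paired reads
covering one spacer each, and per-plot soil/vegetation metadata with a
planted correlation to AMF abundance.

The biology it emulates: arbuscular mycorrhizal fungi are heterokaryotic --
one individual carries a cloud of divergent rDNA ribotypes -- so each
species is represented by several variants around its reference sequence;
soil libraries are dominated by non-Glomeromycota fungi (the background
fraction); PCR produces two-parent single-crossover chimeras; and rare true
variants appear as singleton reads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .readprep import DEFAULT_PRIMERS, FastqRead, reverse_complement

__all__ = [
    "RefTaxon",
    "SimConfig",
    "ReferenceDatabase",
    "ReadSet",
    "SPACER_ANCHORS",
    "generate_reference_db",
    "simulate_reads",
    "simulate_metadata",
]

_BASES = np.array(list("ACGT"))

# Conserved rRNA blocks flanking the spacers (fixed across all simulations;
# these play the role of the 18S tail, 5.8S and 28S head).  The primer
# annealing sites are embedded so that amplicons start/end on the primers.
CONS0 = "TTGTCATTTC"
CONS_A = "GGGATACACGTGACT"
CONS_B = "AATCAAGAATTA"
CONS_C = "TGACGAGA"
CONS_D = "CCATGTTTGTCA"
CONS_E = "GCATTTAAAAATGGG"
CONS_F = "GCATACTTAC"

_ITS5, _ITS2RK = DEFAULT_PRIMERS["ITS1"]
_ITS3, _ITS4 = DEFAULT_PRIMERS["ITS2"]

#: Conserved anchors immediately flanking each spacer in the amplicon after
#: primer removal; used by reference-free rRNA trimming.
SPACER_ANCHORS = {
    "ITS1": (CONS_A, CONS_B),
    "ITS2": (CONS_D, CONS_E),
}

_BIOTOPE_ALTITUDE = {
    "river_valley": (750.0, 1350.0),
    "forest": (1500.0, 1950.0),
    "subalpine_meadow": (2100.0, 2450.0),
}


@dataclass
class RefTaxon:
    """A reference rDNA construct with its lineage and spacer coordinates."""

    accession: str
    lineage: tuple[str, str, str, str, str, str]  # phylum..species
    region_bounds: dict[str, tuple[int, int]]  # 0-based half-open
    sequence: str

    def __post_init__(self) -> None:
        if len(self.lineage) != 6:
            raise ValueError("lineage must have exactly 6 ranks")
        spans = sorted(self.region_bounds.values())
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if e1 > s2:
                raise ValueError("region bounds overlap")
        for s, e in spans:
            if not (0 <= s < e <= len(self.sequence)):
                raise ValueError("region bounds outside sequence")

    def spacer(self, region: str) -> str:
        s, e = self.region_bounds[region]
        return self.sequence[s:e]

    @property
    def genus(self) -> str:
        return self.lineage[4]

    @property
    def species(self) -> str:
        return self.lineage[5]


@dataclass
class SimConfig:
    seed: int = 0
    n_genera: int = 4
    species_per_genus: int = 3
    inter_species_divergence: float = 0.10
    intra_species_divergence: float = 0.005
    ribotypes_per_species: int = 3
    n_background_taxa: int = 8
    background_fraction: float = 0.3
    chimera_rate: float = 0.02
    singleton_rate: float = 0.05
    depth_per_sample: int | Sequence[int] = 400
    n_samples: int = 9
    biotope_labels: tuple[str, ...] = ("subalpine_meadow", "forest", "river_valley")
    its1_fraction: float = 0.5
    spacer_length: int = 170
    read_length: int = 180
    bad_quality_fraction: float = 0.03
    q_good: int = 38
    q_bad: int = 12
    r_target: float = 0.8

    def validate(self) -> None:
        for name in ("background_fraction", "chimera_rate", "singleton_rate", "its1_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.intra_species_divergence < self.inter_species_divergence:
            raise ValueError(
                "intra-species divergence must be smaller than inter-species "
                "divergence for species to be distinguishable"
            )
        if abs(self.r_target) >= 1.0:
            raise ValueError("|r_target| must be < 1")
        if self.n_genera < 1 or self.species_per_genus < 1 or self.n_samples < 1:
            raise ValueError("counts must be positive")


@dataclass
class ReferenceDatabase:
    amf: list[RefTaxon]
    background: list[RefTaxon]

    @property
    def all_taxa(self) -> list[RefTaxon]:
        return self.amf + self.background

    def taxonomy_table(self) -> pd.DataFrame:
        rows = [
            (t.accession, *t.lineage)
            for t in self.all_taxa
        ]
        return pd.DataFrame(
            rows,
            columns=["accession", "phylum", "class", "order", "family", "genus", "species"],
        )

    def amf_centroids(self, region: str) -> list[tuple[str, str]]:
        """(accession, primer-stripped amplicon spacer-with-flanks) per AMF reference."""
        return [(t.accession, _stripped_amplicon(t, region)) for t in self.amf]


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, n)])


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _mutate_exact(rng: np.random.Generator, seq: str, k: int) -> str:
    """Exactly ``k`` substitutions at distinct random positions."""
    if k <= 0:
        return seq
    arr = list(seq)
    for i in rng.choice(len(arr), size=min(k, len(arr)), replace=False):
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _star_rate(target_pairwise: float) -> float:
    """Per-lineage substitution rate on a star tree giving an expected
    pairwise p-distance of ``target_pairwise``.

    Two lineages mutated independently at rate m differ per site with
    probability 2m(1-m) + (2/3)m^2; solve for m.
    """
    if target_pairwise <= 0:
        return 0.0
    a, b, c = -4.0 / 3.0, 2.0, -target_pairwise
    disc = b * b - 4 * a * c
    return (-b + math.sqrt(disc)) / (2 * a)


def _construct(its1: str, its2: str) -> tuple[str, dict[str, tuple[int, int]]]:
    parts = [
        CONS0, _ITS5, CONS_A,                 # 18S tail with forward primer site
        its1,
        CONS_B, reverse_complement(_ITS2RK), CONS_C, _ITS3, CONS_D,  # 5.8S
        its2,
        CONS_E, reverse_complement(_ITS4), CONS_F,  # 28S head
    ]
    seq = "".join(parts)
    s1 = len(CONS0) + len(_ITS5) + len(CONS_A)
    e1 = s1 + len(its1)
    s2 = e1 + len(CONS_B) + len(_ITS2RK) + len(CONS_C) + len(_ITS3) + len(CONS_D)
    e2 = s2 + len(its2)
    return seq, {"ITS1": (s1, e1), "ITS2": (s2, e2)}


def _amplicon(construct: str, bounds: dict[str, tuple[int, int]], region: str) -> str:
    if region == "ITS1":
        start = len(CONS0)  # forward primer start
        end = bounds["ITS1"][1] + len(CONS_B) + len(_ITS2RK)
    else:
        s2 = bounds["ITS2"][0]
        start = s2 - len(CONS_D) - len(_ITS3)
        end = bounds["ITS2"][1] + len(CONS_E) + len(_ITS4)
    return construct[start:end]


def _stripped_amplicon(taxon: RefTaxon, region: str) -> str:
    """Amplicon with both primers removed: flank + spacer + flank."""
    amp = _amplicon(taxon.sequence, taxon.region_bounds, region)
    fwd, rev = DEFAULT_PRIMERS[region]
    return amp[len(fwd) : len(amp) - len(rev)]


def generate_reference_db(config: SimConfig) -> ReferenceDatabase:
    """Synthetic reference database: genera of related species plus background.

    Species within a genus radiate from a genus ancestor on a star tree so
    that expected pairwise spacer p-distance equals the configured
    inter-species divergence; background taxa are unrelated non-Glomeromycota
    lineages.  Deterministic for a given (seed, config).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    m = _star_rate(config.inter_species_divergence)
    amf: list[RefTaxon] = []
    for g in range(config.n_genera):
        genus = f"Glomusopsis{g + 1:02d}"
        anc1 = _rand_seq(rng, config.spacer_length + int(rng.integers(0, 21)))
        anc2 = _rand_seq(rng, config.spacer_length + int(rng.integers(0, 21)))
        for k in range(config.species_per_genus):
            its1 = _mutate(rng, anc1, m)
            its2 = _mutate(rng, anc2, m)
            seq, bounds = _construct(its1, its2)
            acc = f"AMF{g + 1:02d}{k + 1:02d}"
            amf.append(
                RefTaxon(
                    accession=acc,
                    lineage=(
                        "Glomeromycota",
                        "Glomeromycetes",
                        "Glomerales",
                        f"Glomusopsidaceae{g + 1:02d}",
                        genus,
                        f"{genus} species{k + 1}",
                    ),
                    region_bounds=bounds,
                    sequence=seq,
                )
            )
    background: list[RefTaxon] = []
    for b in range(config.n_background_taxa):
        its1 = _rand_seq(rng, config.spacer_length + int(rng.integers(0, 21)))
        its2 = _rand_seq(rng, config.spacer_length + int(rng.integers(0, 21)))
        seq, bounds = _construct(its1, its2)
        background.append(
            RefTaxon(
                accession=f"BG{b + 1:04d}",
                lineage=(
                    "Ascomycota",
                    "Sordariomycetes",
                    "Hypocreales",
                    f"Backgroundaceae{b + 1:02d}",
                    f"Fuscomyces{b + 1:02d}",
                    f"Fuscomyces{b + 1:02d} sp{b + 1}",
                ),
                region_bounds=bounds,
                sequence=seq,
            )
        )
    return ReferenceDatabase(amf, background)


@dataclass
class ReadSet:
    """Paired reads plus the per-read truth table and per-sample AMF truth."""

    pairs: list[tuple[FastqRead, FastqRead]]
    truth: pd.DataFrame
    sample_ids: list[str]
    biotopes: dict[str, str]
    amf_reads_per_sample: pd.Series
    species_profiles: pd.DataFrame  # samples x species expected relative weight


def _build_ribotypes(
    rng: np.random.Generator, db: ReferenceDatabase, config: SimConfig
) -> dict[str, dict[str, list[str]]]:
    """Per species and region: ribotype amplicon variants.

    Ribotype 0 is the reference amplicon itself; each further ribotype
    carries exactly ``round(intra_species_divergence * spacer_length)``
    substitutions confined to the spacer (the heterokaryotic ribotype
    cloud).  The substitution count is fixed rather than binomial so the
    configured divergence is a hard bound, and the primer/flank sites stay
    intact: variants that broke a primer site would not amplify at all.
    """
    fwd1, rev1 = DEFAULT_PRIMERS["ITS1"]
    fwd2, rev2 = DEFAULT_PRIMERS["ITS2"]
    # spacer offsets within each region's amplicon
    offsets = {
        "ITS1": (len(fwd1) + len(CONS_A), len(CONS_B) + len(rev1)),
        "ITS2": (len(fwd2) + len(CONS_D), len(CONS_E) + len(rev2)),
    }
    out: dict[str, dict[str, list[str]]] = {}
    for t in db.all_taxa:
        out[t.species] = {}
        for region in ("ITS1", "ITS2"):
            amp = _amplicon(t.sequence, t.region_bounds, region)
            lo, hi_off = offsets[region]
            hi = len(amp) - hi_off
            spacer = amp[lo:hi]
            k = int(round(config.intra_species_divergence * len(spacer)))
            variants = [amp]
            for _ in range(max(config.ribotypes_per_species - 1, 0)):
                mutated = _mutate_exact(rng, spacer, max(k, 1))
                variants.append(amp[:lo] + mutated + amp[hi:])
            out[t.species][region] = variants
    return out


def _make_pair(
    rng: np.random.Generator,
    read_id: str,
    sample_id: str,
    amplicon: str,
    config: SimConfig,
) -> tuple[FastqRead, FastqRead]:
    L = min(config.read_length, len(amplicon))

    def one(template: str) -> tuple[str, list[int]]:
        qual = np.where(
            rng.random(L) < config.bad_quality_fraction, config.q_bad, config.q_good
        )
        arr = list(template[:L])
        err = rng.random(L) < 10.0 ** (-qual / 10.0)
        for i in np.nonzero(err)[0]:
            choices = [b for b in "ACGT" if b != arr[i]]
            arr[i] = choices[rng.integers(0, 3)]
        return "".join(arr), [int(q) for q in qual]

    s1, q1 = one(amplicon)
    s2, q2 = one(reverse_complement(amplicon))
    return (
        FastqRead(read_id, s1, q1, sample_id),
        FastqRead(read_id, s2, q2, sample_id),
    )


def simulate_reads(config: SimConfig, db: ReferenceDatabase) -> ReadSet:
    """Per-sample paired reads with a complete per-read truth table.

    Each read pair covers one spacer region.  A configurable fraction of
    reads come from background (non-Glomeromycota) taxa; chimeras are
    single-crossover recombinants of two same-region amplicons with the
    breakpoint uniform in the middle 50%; singleton reads carry two private
    substitutions so they dereplicate to abundance one.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    ribo = _build_ribotypes(rng, db, config)
    amf_species = [t.species for t in db.amf]
    bg_species = [t.species for t in db.background]

    sample_ids = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    biotopes = {
        s: config.biotope_labels[i % len(config.biotope_labels)]
        for i, s in enumerate(sample_ids)
    }
    if isinstance(config.depth_per_sample, int):
        depths = [config.depth_per_sample] * config.n_samples
    else:
        depths = list(config.depth_per_sample)
        if len(depths) != config.n_samples:
            raise ValueError("depth list length must equal n_samples")

    # biotope-level species weights shared within a biotope (community
    # structure the ordination/ANOSIM stages should recover) with mild
    # per-sample lognormal jitter
    biotope_base = {
        b: rng.lognormal(0.0, 1.0, len(amf_species)) for b in config.biotope_labels
    }
    bg_base = {
        b: rng.lognormal(0.0, 1.0, max(len(bg_species), 1))
        for b in config.biotope_labels
    }
    profiles = {}
    bg_profiles = {}
    for s in sample_ids:
        w = biotope_base[biotopes[s]] * rng.lognormal(0.0, 0.4, len(amf_species))
        profiles[s] = w / w.sum()
        wb = bg_base[biotopes[s]] * rng.lognormal(0.0, 0.4, max(len(bg_species), 1))
        bg_profiles[s] = wb / wb.sum()
    species_profiles = pd.DataFrame(profiles, index=amf_species).T

    pairs: list[tuple[FastqRead, FastqRead]] = []
    rows = []
    counter = 0
    for s, depth in zip(sample_ids, depths):
        for _ in range(depth):
            counter += 1
            rid = f"read{counter:07d}"
            region = "ITS1" if rng.random() < config.its1_fraction else "ITS2"
            is_bg = rng.random() < config.background_fraction and bg_species
            if is_bg:
                species = str(rng.choice(bg_species, p=bg_profiles[s]))
                rt = 0
            else:
                species = str(
                    rng.choice(amf_species, p=species_profiles.loc[s].to_numpy())
                )
                rt = int(rng.integers(0, max(config.ribotypes_per_species, 1)))
            amp = ribo[species][region][rt]
            is_chimera = bool(rng.random() < config.chimera_rate)
            parent2 = ""
            if is_chimera:
                pool = bg_species if is_bg else amf_species
                others = [x for x in pool if x != species] or [species]
                parent2 = others[rng.integers(0, len(others))]
                amp2 = ribo[parent2][region][0]
                lo = int(0.25 * min(len(amp), len(amp2)))
                hi = int(0.75 * min(len(amp), len(amp2)))
                x = int(rng.integers(lo, max(hi, lo + 1)))
                amp = amp[:x] + amp2[x:]
            is_singleton = bool(rng.random() < config.singleton_rate)
            if is_singleton:
                pos = rng.choice(len(amp), size=min(2, len(amp)), replace=False)
                arr = list(amp)
                for i in pos:
                    choices = [b for b in "ACGT" if b != arr[i]]
                    arr[i] = choices[rng.integers(0, 3)]
                amp = "".join(arr)
            r1, r2 = _make_pair(rng, rid, s, amp, config)
            pairs.append((r1, r2))
            rows.append(
                (rid, s, species, parent2, rt, region, is_chimera, is_singleton, bool(is_bg))
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "sample_id", "taxon", "chimera_parent2", "ribotype",
            "region", "is_chimera", "is_singleton", "is_background",
        ],
    )
    amf_reads = (
        truth[~truth.is_background].groupby("sample_id").size().reindex(sample_ids, fill_value=0)
    )
    return ReadSet(pairs, truth, sample_ids, biotopes, amf_reads, species_profiles)


def simulate_metadata(
    config: SimConfig,
    amf_abundance: pd.Series,
    biotopes: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-plot metadata with a planted Pearson correlation to AMF abundance.

    ``percent_annual_plants`` is a linear Gaussian blend with the
    standardized abundance vector, so its sample Pearson correlation with
    abundance is centred on ``r_target``.  Altitude is drawn from disjoint
    biotope bands (valley < forest < meadow).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    samples = list(amf_abundance.index)
    n = len(samples)
    if biotopes is None:
        biotopes = {
            s: config.biotope_labels[i % len(config.biotope_labels)]
            for i, s in enumerate(samples)
        }
    x = amf_abundance.to_numpy(dtype=float)
    sd = x.std()
    z = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
    r = config.r_target
    blend = r * z + math.sqrt(1 - r * r) * rng.standard_normal(n)
    percent_annual = np.clip(50 + 14 * blend, 0, 100)

    rows = []
    for i, s in enumerate(samples):
        b = biotopes[s]
        lo, hi = _BIOTOPE_ALTITUDE.get(b, (1000.0, 2000.0))
        rows.append(
            {
                "stp_id": s,
                "biotope": b,
                "altitude_m": float(rng.uniform(lo, hi)),
                "pH_KCl": float(rng.uniform(4.0, 7.5)),
                "Pi_mg_per_kg": float(rng.uniform(5.0, 60.0)),
                "N_total_pct": float(rng.uniform(0.1, 1.2)),
                "P_total_pct": float(rng.uniform(0.05, 0.4)),
                "percent_annual_plants": float(percent_annual[i]),
                "n_herb_species": int(rng.integers(10, 60)),
                "fraction_lt_0_01mm": float(rng.uniform(0.1, 0.7)),
                "soil_type_code": int(rng.integers(1, 6)),
            }
        )
    return pd.DataFrame(rows).set_index("stp_id")
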