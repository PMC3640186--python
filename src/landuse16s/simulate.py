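"""Synthetic study generator: reference taxonomy, soils, communities, reads.

Everything the pipeline consumes is generated here, deterministically from
a seed, with the statistical structure of a multi-site agricultural /
non-agricultural soil survey planted in:

* a toy three-phylum reference taxonomy whose sequence divergences make
  every rank identity threshold decisive (within-family inter-genus
  identity in [0.90, 0.95), cross-phylum identity < 0.80);
* soil covariates with higher pH on agricultural plots and NH3 derived
  from NH4+-N and pH by speciation;
* per-sample communities in which one focal genus (an ammonia-oxidizing
  archaeon, ``Nitrososphaera``) increases and one (``Bradyrhizobium``)
  decreases with pH — and hence with agricultural land use;
* barcoded paired reads (inline 8-base sample barcode + 11-base primer
  proxy on the forward mate) with uniform per-base substitution errors.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .reads import ReadPair, encode_quals
from .align import revcomp
from .soil import nh3_from_nh4, som_from_oc
from .taxonomy import (
    ReferenceDatabase,
    ReferenceRecord,
    TaxonomicLineage,
)

PRIMER_PROXY = "GTGCCAGCAGC"  # first 11 bases of the 515F primer
SITE_NAMES = ("BRR", "EAA", "KBS")
FOCAL_AOA = "Nitrososphaera"
FOCAL_BRADY = "Bradyrhizobium"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_sites: int = 3
    n_samples_per_group: int = 16
    n_genera: int = 12
    reads_per_sample: int = 2000
    read_length: int = 150
    ref_length: int = 300
    substitution_error_rate: float = 0.005
    barcode_length: int = 8
    primer_prefix_length: int = 11
    effect_aoa: float = 1.0  # slope of focal-genus-1 log-abundance on pH
    effect_brady: float = -1.0  # slope of focal-genus-2 log-abundance on pH
    focal_base_weight: float = 0.02
    community_noise_sd: float = 0.3
    base_quality: int = 40
    tail_quality: int = 2
    low_quality_tail: int = 0  # length of the low-quality 3' tail

    def __post_init__(self) -> None:
        counts = (
            self.n_sites,
            self.n_samples_per_group,
            self.n_genera,
            self.reads_per_sample,
            self.read_length,
            self.ref_length,
            self.barcode_length,
        )
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be positive")
        if self.n_genera < 4:
            raise ValueError("n_genera must be >= 4")
        if not (0 <= self.substitution_error_rate < 1):
            raise ValueError("substitution_error_rate must be in [0, 1)")
        if self.read_length <= self.barcode_length + self.primer_prefix_length:
            raise ValueError("read_length must exceed barcode + primer prefix")


@dataclass(frozen=True)
class CommunityProfile:
    sample: str
    genera: tuple[str, ...]
    proportions: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("proportions must be non-negative and sum to 1")


@dataclass(frozen=True)
class SoilSample:
    sample: str
    site: str
    land_use: int  # 1 = agricultural, 0 = non-agricultural
    ph: float
    nh4_n: float
    no3_n: float
    total_n: float
    moisture: float
    som: float
    nh3: float
    log_nh3: float

    def __post_init__(self) -> None:
        if not (3.0 < self.ph < 10.0):
            raise ValueError(f"{self.sample}: pH out of (3, 10)")
        if self.nh4_n < 0 or self.nh3 > self.nh4_n + 1e-12:
            raise ValueError(f"{self.sample}: need 0 <= nh3 <= nh4_n")
        if self.land_use not in (0, 1):
            raise ValueError("land_use must be 0 or 1")


def _rng(config: SimulationConfig, *stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed % (2**31), *stream])


# ----------------------------------------------------------- reference db

# genus allocation order: focal genera first so n_genera >= 4 always plants both
_GENUS_POOL: tuple[tuple[str, str, str], ...] = (
    # (genus, phylum key, family)
    (FOCAL_AOA, "thaum", "Nitrososphaeraceae"),
    (FOCAL_BRADY, "proteo", "Bradyrhizobiaceae"),
    ("Nitrosocosmicus", "thaum", "Nitrososphaeraceae"),
    ("Rhodopseudomonas", "proteo", "Bradyrhizobiaceae"),
    ("Nocardioides", "actino", "Nocardioidaceae"),
    ("Hyphomicrobium", "proteo", "Hyphomicrobiaceae"),
    ("Marmoricola", "actino", "Nocardioidaceae"),
    ("Nitrobacter", "proteo", "Bradyrhizobiaceae"),
    ("Rhodoplanes", "proteo", "Hyphomicrobiaceae"),
    ("Aeromicrobium", "actino", "Nocardioidaceae"),
    ("Pedomicrobium", "proteo", "Hyphomicrobiaceae"),
    ("Micromonospora", "actino", "Micromonosporaceae"),
    ("Actinoplanes", "actino", "Micromonosporaceae"),
)

_PHYLA = {
    "thaum": ("Archaea", "Thaumarchaeota", "Nitrososphaeria", "Nitrososphaerales"),
    "proteo": ("Bacteria", "Proteobacteria", "Alphaproteobacteria", "Rhizobiales"),
    "actino": ("Bacteria", "Actinobacteria", "Actinomycetia", "Propionibacteriales"),
}

FAMILY_DIVERGENCE = 0.065  # per-base mutation rate family ancestor vs phylum root
GENUS_DIVERGENCE = 0.0385  # per-base mutation rate genus vs family ancestor
_MAX_ATTEMPTS = 40


def genus_table(n_genera: int) -> list[tuple[str, str, str]]:
    """(genus, phylum key, family) rows for the first ``n_genera`` genera."""
    rows = list(_GENUS_POOL)
    for i in range(len(rows), n_genera):
        rows.append((f"Genus{i + 1}", "actino", "Micromonosporaceae"))
    return rows[:n_genera]


def genus_names(n_genera: int) -> tuple[str, ...]:
    return tuple(g for g, _, _ in genus_table(n_genera))


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = np.nonzero(rng.random(seq.shape[0]) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _identity(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.mean(a == b))


def generate_reference_db(config: SimulationConfig) -> ReferenceDatabase:
    """One full-lineage record per genus with controlled divergence bands.

    Retries (bounded, seed-deterministic) until within-family inter-genus
    identity lands in [0.90, 0.95) and cross-phylum identity is < 0.80.
    """
    table = genus_table(config.n_genera)
    for attempt in range(_MAX_ATTEMPTS):
        rng = _rng(config, 1, attempt)
        roots = {k: rng.integers(0, 4, config.ref_length) for k in _PHYLA}
        roots = {k: _BASES[v] for k, v in roots.items()}
        fam_seqs: dict[str, np.ndarray] = {}
        seqs: dict[str, np.ndarray] = {}
        for genus, pk, family in table:
            if family not in fam_seqs:
                fam_seqs[family] = _mutate(roots[pk], FAMILY_DIVERGENCE, rng)
            seqs[genus] = _mutate(fam_seqs[family], GENUS_DIVERGENCE, rng)
        if _divergence_ok(table, seqs):
            break
    else:
        raise RuntimeError("could not satisfy divergence targets after bounded retries")

    records = []
    for i, (genus, pk, family) in enumerate(table):
        dom, phy, cls, order = _PHYLA[pk]
        lineage = TaxonomicLineage((dom, phy, cls, order, family, genus, f"{genus} sp1"))
        seq = "".join(map(chr, seqs[genus]))
        records.append(ReferenceRecord(id=f"R{i + 1:03d}", lineage=lineage, sequence=seq))
    return ReferenceDatabase(records)


def _divergence_ok(table, seqs) -> bool:
    for (g1, p1, f1), (g2, p2, f2) in product(table, repeat=2):
        if g1 >= g2:
            continue
        ident = _identity(seqs[g1], seqs[g2])
        if f1 == f2 and not (0.90 <= ident < 0.95):
            return False
        if p1 != p2 and ident >= 0.80:
            return False
    return True


# ------------------------------------------------------------------- soils

_SITE_PH_OFFSET = {"BRR": 0.2, "EAA": 0.1, "KBS": -0.3}
_SITE_MOISTURE = {"BRR": 20.0, "EAA": 110.0, "KBS": 18.0}


def site_names(n_sites: int) -> tuple[str, ...]:
    names = list(SITE_NAMES[:n_sites])
    for i in range(len(names), n_sites):
        names.append(f"S{i + 1}")
    return tuple(names)


def generate_soil_covariates(config: SimulationConfig) -> list[SoilSample]:
    """Agricultural plots higher in pH (7.4 +- 0.3 vs 5.6 +- 0.3), NH3 derived."""
    rng = _rng(config, 2)
    out: list[SoilSample] = []
    for site in site_names(config.n_sites):
        ph_off = _SITE_PH_OFFSET.get(site, 0.0)
        moist_base = _SITE_MOISTURE.get(site, 25.0)
        for land_use, tag, ph_mean in ((1, "AG", 7.4), (0, "NA", 5.6)):
            for i in range(config.n_samples_per_group):
                ph = float(np.clip(rng.normal(ph_mean + ph_off, 0.3), 3.5, 9.5))
                nh4 = float(np.clip(rng.lognormal(np.log(4.0), 0.4), 0.5, 12.0))
                no3 = float(np.clip(rng.lognormal(np.log(10.0), 0.7), 0.5, 100.0))
                total_n = float(np.clip(rng.normal(0.2, 0.06), 0.03, 0.5))
                moisture = float(max(rng.normal(moist_base, 3.0), 2.0))
                oc = float(
                    np.clip(rng.normal(1.5 if land_use else 3.5, 0.4), 0.2, 6.0)
                )
                nh3, log_nh3 = nh3_from_nh4(nh4, ph)
                out.append(
                    SoilSample(
                        sample=f"{site}_{tag}{i + 1:02d}",
                        site=site,
                        land_use=land_use,
                        ph=ph,
                        nh4_n=nh4,
                        no3_n=no3,
                        total_n=total_n,
                        moisture=moisture,
                        som=float(som_from_oc(oc)),
                        nh3=nh3,
                        log_nh3=log_nh3,
                    )
                )
    return out


def soil_table(samples: list[SoilSample]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in samples]).set_index("sample")


# -------------------------------------------------------------- communities


def generate_community(
    soil: SoilSample, config: SimulationConfig, rng: np.random.Generator | None = None
) -> CommunityProfile:
    """Community with focal genera responding (oppositely) to pH.

    Focal weights are ``base * exp(effect * (pH - 6.5) + noise)``; the
    remaining genera share a symmetric Dirichlet bulk.  Deterministic given
    the config seed and the sample id.
    """
    if rng is None:
        rng = _rng(config, 3, zlib.crc32(soil.sample.encode()))
    genera = genus_names(config.n_genera)
    x = soil.ph - 6.5
    noise = rng.normal(0.0, config.community_noise_sd, size=2)
    w = np.empty(len(genera))
    bulk = rng.dirichlet(np.ones(len(genera) - 2)) * (1.0 - 2 * config.focal_base_weight)
    i_aoa = genera.index(FOCAL_AOA)
    i_brady = genera.index(FOCAL_BRADY)
    others = [i for i in range(len(genera)) if i not in (i_aoa, i_brady)]
    w[i_aoa] = config.focal_base_weight * np.exp(config.effect_aoa * x + noise[0])
    w[i_brady] = config.focal_base_weight * np.exp(config.effect_brady * x + noise[1])
    w[others] = bulk
    return CommunityProfile(sample=soil.sample, genera=genera, proportions=w / w.sum())


# ------------------------------------------------------------------- reads


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.shape[0]) < rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = rng.choice(choices)
    return arr.tobytes().decode("ascii")


def generate_reads(
    profile: CommunityProfile,
    db: ReferenceDatabase,
    config: SimulationConfig,
    barcode: str,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadPair], dict[str, str]]:
    """Barcoded paired reads for one sample plus a read-id -> source truth map.

    Forward mate: barcode + 11-base primer proxy + 5' window of the source
    record; reverse mate: reverse complement of the 3' window.  Substitution
    errors hit every position (barcode included) at the configured rate.
    """
    if rng is None:
        rng = _rng(config, 4, zlib.crc32(profile.sample.encode()))
    if len(barcode) != config.barcode_length:
        raise ValueError("barcode length does not match config")
    by_genus = {r.genus: r for r in db}
    missing = [g for g in profile.genera if g not in by_genus]
    if missing:
        raise ValueError(f"profile genera not in reference db: {missing}")

    fwd_template_len = config.read_length - config.barcode_length - config.primer_prefix_length
    if fwd_template_len <= 0 or config.read_length > config.ref_length:
        raise ValueError("read_length incompatible with reference length")

    qual = _quality_string(config)
    sources = rng.choice(len(profile.genera), size=config.reads_per_sample, p=profile.proportions)
    pairs: list[ReadPair] = []
    truth: dict[str, str] = {}
    primer = PRIMER_PROXY[: config.primer_prefix_length]
    for i, gi in enumerate(sources):
        rec = by_genus[profile.genera[gi]]
        rid = f"{profile.sample}:{i + 1:06d}"
        fwd = barcode + primer + rec.sequence[:fwd_template_len]
        rev = revcomp(rec.sequence[-config.read_length :])
        fwd = _apply_errors(fwd, config.substitution_error_rate, rng)
        rev = _apply_errors(rev, config.substitution_error_rate, rng)
        pairs.append(ReadPair(id=rid, fwd_seq=fwd, rev_seq=rev, fwd_qual=qual, rev_qual=qual))
        truth[rid] = rec.id
    return pairs, truth


def _quality_string(config: SimulationConfig) -> str:
    q = [config.base_quality] * config.read_length
    if config.low_quality_tail > 0:
        tail = min(config.low_quality_tail, config.read_length)
        q[config.read_length - tail :] = [config.tail_quality] * tail
    return encode_quals(q)


def generate_barcodes(config: SimulationConfig, samples: list[str]) -> dict[str, str]:
    """Unique fixed-length barcodes per sample, deterministic given the seed."""
    rng = _rng(config, 5)
    seen: set[str] = set()
    out: dict[str, str] = {}
    for s in samples:
        while True:
            bc = "".join("ACGT"[i] for i in rng.integers(0, 4, config.barcode_length))
            if bc not in seen:
                seen.add(bc)
                out[bc] = s
                break
    return out


def sample_sheet(
    soils: list[SoilSample], barcodes: dict[str, str]
) -> pd.DataFrame:
    """sample, barcode, site, land_use — the demultiplexing sheet."""
    bc_by_sample = {s: b for b, s in barcodes.items()}
    rows = [
        {
            "sample": s.sample,
            "barcode": bc_by_sample[s.sample],
            "site": s.site,
            "land_use": s.land_use,
        }
        for s in soils
    ]
    return pd.DataFrame(rows).set_index("sample")
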