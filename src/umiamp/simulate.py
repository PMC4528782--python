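"""Synthetic barcoded-amplicon read generator with known truth.

The generator emulates the molecular process end to end: each original
molecule of a panel amplicon independently carries each specified variant
(a homozygous variant in an admixed genome contributes carriers at the
mixture fraction, a heterozygous one at half of it), receives a uniform
random UMI in the single barcode-assignment cycle (collisions are allowed
and recorded), and is amplified stochastically — reads per molecule are
Poisson with a per-molecule lognormal amplification factor, reflecting the
multiplicative compounding of per-cycle efficiency differences over many
universal-PCR cycles.  Reads carry PCR errors accumulated over a simplified
binary duplication lineage, then per-base sequencing errors with Gaussian
phred qualities truncated to [2, 41].

Every run writes a truth table (molecule id, amplicon, true barcode, variant
flags, reads emitted) so that pipeline recovery, consensus accuracy and
detection power can all be measured against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .panel import Panel, revcomp
from .preprocess import SequencedRead
from .quantify import molecule_table

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i

QUAL_MIN, QUAL_MAX = 2, 41


@dataclass(frozen=True)
class VariantSpec:
    """A variant carried by a fraction of molecules of one amplicon.

    If ``molecule_fraction`` is None the carrier probability derives from the
    admixture: ``mixture_fraction`` for a homozygous variant, half of it for a
    heterozygous one.
    """

    amplicon_id: str
    offset: int  # 0-based within the amplicon insert
    alt: str
    molecule_fraction: Optional[float] = None
    zygosity: str = "het"

    def __post_init__(self):
        if self.zygosity not in ("het", "hom"):
            raise ValueError("zygosity must be 'het' or 'hom'")
        if self.alt not in "ACGT" or len(self.alt) != 1:
            raise ValueError("alt must be a single ACGT base")

    @property
    def key(self) -> str:
        return f"{self.amplicon_id}:{self.offset}{self.alt}"

    def carrier_probability(self, mixture_fraction: float) -> float:
        if self.molecule_fraction is not None:
            return self.molecule_fraction
        return mixture_fraction * (1.0 if self.zygosity == "hom" else 0.5)


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment."""

    panel: Panel
    molecules_per_amplicon: Union[int, dict[str, int]] = 500
    variants: tuple[VariantSpec, ...] = ()
    mixture_fraction: float = 0.02
    umi_length: int = 10
    mean_reads_per_molecule: float = 10.0
    amplification_dispersion: float = 2.0  # lognormal sigma of the per-molecule factor
    pcr_error_rate: float = 1e-4  # per base per duplication generation
    seq_error_rate: float = 1e-3  # per base
    quality_mean: float = 33.0
    quality_sd: float = 3.0
    seed: int = 0
    deterministic: bool = False  # fixed reads/molecule, no amplification noise

    def __post_init__(self):
        if not 0 <= self.mixture_fraction <= 1:
            raise ValueError("mixture_fraction must be in [0, 1]")
        for name in ("pcr_error_rate", "seq_error_rate"):
            rate = getattr(self, name)
            if not 0 <= rate <= 0.1:
                raise ValueError(f"{name} must be in [0, 0.1]")
        if not 6 <= self.umi_length <= 12:
            raise ValueError("umi_length must be in [6, 12]")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    def n_molecules(self, amplicon_id: str) -> int:
        if isinstance(self.molecules_per_amplicon, dict):
            return self.molecules_per_amplicon[amplicon_id]
        return self.molecules_per_amplicon


@dataclass
class Molecule:
    """One original (pre-PCR) barcoded molecule."""

    molecule_id: str
    amplicon_id: str
    barcode: str
    insert: str
    variant_flags: dict[str, bool] = field(default_factory=dict)


@dataclass
class TruthRecord:
    molecule_id: str
    amplicon_id: str
    true_barcode: str
    variant_flags: dict[str, bool]
    reads_emitted: int


@dataclass
class SimOutput:
    """Reads plus ground truth for one simulated library."""

    reads1: list[SequencedRead]
    reads2: list[SequencedRead]
    truth: list[TruthRecord]

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truth:
            row = {
                "molecule_id": t.molecule_id,
                "amplicon_id": t.amplicon_id,
                "barcode": t.true_barcode,
                "reads_emitted": t.reads_emitted,
            }
            for k, v in t.variant_flags.items():
                row[f"variant:{k}"] = int(v)
            rows.append(row)
        return pd.DataFrame(rows)


def _random_umi(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def _mutate(arr: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base independently with probability p (uniform over the
    three other bases)."""
    if p <= 0:
        return arr
    mask = rng.random(arr.size) < p
    n = int(mask.sum())
    if n == 0:
        return arr
    out = arr.copy()
    shift = rng.integers(1, 4, size=n)
    out[mask] = _BASES[(_BASE_INDEX[out[mask]] + shift) % 4]
    return out


def simulate_molecules(
    config: SimConfig, rng: Optional[np.random.Generator] = None
) -> list[Molecule]:
    """Draw the original molecules for every panel amplicon.

    Each molecule independently carries each variant of its amplicon with the
    variant's carrier probability and gets a uniform random UMI (collisions
    allowed; they are visible in the truth table as repeated barcodes).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    by_amp: dict[str, list[VariantSpec]] = {}
    for v in config.variants:
        amp = config.panel.get(v.amplicon_id)
        if amp.insert_sequence is None or not 0 <= v.offset < len(amp.insert_sequence):
            raise ValueError(f"variant {v.key}: offset outside amplicon insert")
        by_amp.setdefault(v.amplicon_id, []).append(v)
    molecules: list[Molecule] = []
    for amp in config.panel:
        if amp.insert_sequence is None:
            raise ValueError(f"amplicon {amp.amplicon_id} has no insert_sequence")
        n = config.n_molecules(amp.amplicon_id)
        variants = by_amp.get(amp.amplicon_id, [])
        carries = {
            v.key: rng.random(n) < v.carrier_probability(config.mixture_fraction)
            for v in variants
        }
        for i in range(n):
            insert = amp.insert_sequence
            flags = {}
            for v in variants:
                flags[v.key] = bool(carries[v.key][i])
                if flags[v.key]:
                    insert = insert[: v.offset] + v.alt + insert[v.offset + 1 :]
            molecules.append(
                Molecule(
                    molecule_id=f"{amp.amplicon_id}.m{i}",
                    amplicon_id=amp.amplicon_id,
                    barcode=_random_umi(rng, config.umi_length),
                    insert=insert,
                    variant_flags=flags,
                )
            )
    return molecules


def _emit_read(template: bytes, pcr_p: float, config: SimConfig,
               rng: np.random.Generator, read_id: str) -> SequencedRead:
    arr = np.frombuffer(template, dtype=np.uint8)
    arr = _mutate(arr, pcr_p, rng)
    arr = _mutate(arr, config.seq_error_rate, rng)
    quals = np.clip(
        np.rint(rng.normal(config.quality_mean, config.quality_sd, arr.size)),
        QUAL_MIN, QUAL_MAX,
    ).astype(int)
    return SequencedRead(read_id, bytes(arr).decode(), quals.tolist())


def amplify_and_sequence(
    molecules: Sequence[Molecule],
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> SimOutput:
    """Amplify molecules and emit paired reads.

    Reads per molecule are Poisson(mean * lognormal(0, sigma)); each read
    accumulates PCR errors over a binary duplication lineage of depth
    ceil(log2(reads)) at the per-generation rate, then sequencing errors.
    Read 1 is universal tag + UMI + barcoded primer + insert; read 2 is the
    opposite-side tag + non-barcoded primer + reverse-complemented insert.
    With ``deterministic`` set, every molecule emits exactly
    round(mean_reads_per_molecule) error-free-count reads.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    panel = config.panel
    reads1: list[SequencedRead] = []
    reads2: list[SequencedRead] = []
    truth: list[TruthRecord] = []
    for mol in molecules:
        amp = panel.get(mol.amplicon_id)
        if config.deterministic:
            n_reads = int(round(config.mean_reads_per_molecule))
        else:
            factor = rng.lognormal(0.0, config.amplification_dispersion)
            n_reads = int(rng.poisson(config.mean_reads_per_molecule * factor))
        truth.append(
            TruthRecord(mol.molecule_id, mol.amplicon_id, mol.barcode,
                        dict(mol.variant_flags), n_reads)
        )
        if n_reads == 0:
            continue
        generations = max(1, math.ceil(math.log2(max(n_reads, 2))))
        pcr_p = 1.0 - (1.0 - config.pcr_error_rate) ** generations
        t1 = (panel.universal_tag_bc + mol.barcode + amp.bc_primer.sequence
              + mol.insert).encode()
        t2 = (panel.universal_tag_nonbc + amp.nonbc_primer.sequence
              + revcomp(mol.insert)).encode()
        for j in range(n_reads):
            rid = f"{mol.molecule_id}.r{j}"
            r1 = _emit_read(t1, pcr_p, config, rng, rid)
            r2 = _emit_read(t2, pcr_p, config, rng, rid)
            r1.mate = r2
            reads1.append(r1)
            reads2.append(r2)
    return SimOutput(reads1=reads1, reads2=reads2, truth=truth)


def simulate_library(config: SimConfig) -> SimOutput:
    """Convenience: molecules + amplification in one seeded call."""
    rng = np.random.default_rng(config.seed)
    molecules = simulate_molecules(config, rng)
    return amplify_and_sequence(molecules, config, rng)


def simulate_replicates(config: SimConfig, n_replicates: int) -> list[SimOutput]:
    """Independent replicate libraries sharing expected abundances.

    Per replicate, the molecule count of each amplicon is Poisson around the
    configured expectation (technical replicates resample molecules), then
    amplification and sequencing proceed independently.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    seeds = np.random.SeedSequence(config.seed).spawn(n_replicates)
    outputs = []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        per_amp = {
            a.amplicon_id: (
                config.n_molecules(a.amplicon_id) if config.deterministic
                else int(rng.poisson(config.n_molecules(a.amplicon_id)))
            )
            for a in config.panel
        }
        rep_cfg = replace(config, molecules_per_amplicon=per_amp)
        molecules = simulate_molecules(rep_cfg, rng)
        outputs.append(amplify_and_sequence(molecules, rep_cfg, rng))
    return outputs


def simulate_count_replicates(
    config: SimConfig, n_replicates: int
) -> pd.DataFrame:
    """Counts-level view of :func:`simulate_replicates`: a molecule table with
    per-amplicon barcode counts (molecules that emitted at least one read) and
    raw read counts per replicate, drawn from the same distributions but
    without constructing read sequences.  Barcode collisions and UMI errors
    are not modelled at this level."""
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    seeds = np.random.SeedSequence(config.seed).spawn(n_replicates)
    rows = []
    for r, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        for amp in config.panel:
            m = config.n_molecules(amp.amplicon_id)
            if config.deterministic:
                n_mol = m
                reads = np.full(n_mol, int(round(config.mean_reads_per_molecule)))
            else:
                n_mol = int(rng.poisson(m))
                lam = config.mean_reads_per_molecule * rng.lognormal(
                    0.0, config.amplification_dispersion, n_mol
                )
                reads = rng.poisson(lam)
            rows.append(
                (amp.amplicon_id, f"rep{r + 1}", int((reads > 0).sum()), int(reads.sum()))
            )
    return molecule_table(rows)


def molecule_table_from_truth(
    outputs: Sequence[SimOutput],
) -> pd.DataFrame:
    """Molecule table derived from replicate truth tables (observable truth:
    only molecules with at least one emitted read count as barcodes)."""
    rows = []
    for r, out in enumerate(outputs):
        per_amp: dict[str, list[int]] = {}
        for t in out.truth:
            per_amp.setdefault(t.amplicon_id, []).append(t.reads_emitted)
        for amp_id, reads in sorted(per_amp.items()):
            arr = np.asarray(reads)
            rows.append((amp_id, f"rep{r + 1}", int((arr > 0).sum()), int(arr.sum())))
    return molecule_table(rows)
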