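"""Design and validation of chimeric synthetic spike constructs.

A synthetic spike is an artificial DNA molecule carrying the primer binding
sites (PBSs) of one amplicon family — prokaryotic 16S V4, eukaryotic 18S or
fungal ITS — around a random "stuffer" sequence matched in length and GC
content to the natural amplicon.  Amplified alongside environmental DNA, the
spike behaves like one extra taxon whose input copy number is known, which is
what makes absolute quantitation possible downstream.

The module generates stuffers under composition/motif constraints, assembles
spike amplicons, runs a small IUPAC-aware in-silico PCR, and validates
designs against a whole primer set.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq, reverse_complement
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils import gc_fraction

IUPAC_SETS: Dict[str, frozenset] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_ALPHABET = frozenset(IUPAC_SETS)


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware (delegates to biopython)."""
    return str(reverse_complement(Seq(seq)))


def _check_dna(seq: str, what: str) -> None:
    bad = set(seq.upper()) - IUPAC_ALPHABET
    if bad:
        raise ValueError(f"{what} contains non-IUPAC characters: {sorted(bad)}")


@dataclass(frozen=True)
class PrimerPair:
    """A forward/reverse amplification primer pair for one amplicon family.

    ``name`` doubles as the family key used throughout the package
    (conventionally "P", "E" or "F").  ``amplicon_length_target`` is the
    expected full amplicon size (PBS-inclusive) and
    ``amplicon_length_window`` the inclusive read-length window retained in
    downstream filtering.
    """

    name: str
    forward: str
    reverse: str
    amplicon_length_target: int
    amplicon_length_window: Tuple[int, int]

    def __post_init__(self) -> None:
        if not self.forward or not self.reverse:
            raise ValueError("primers must be non-empty")
        _check_dna(self.forward, "forward primer")
        _check_dna(self.reverse, "reverse primer")
        lo, hi = self.amplicon_length_window
        if not lo <= self.amplicon_length_target <= hi:
            raise ValueError(
                f"amplicon target {self.amplicon_length_target} outside "
                f"window {self.amplicon_length_window}"
            )

    @property
    def stuffer_length(self) -> int:
        """Stuffer length implied by the amplicon target; raises if negative."""
        n = self.amplicon_length_target - len(self.forward) - len(self.reverse)
        if n < 0:
            raise ValueError(
                "primers longer than the amplicon target "
                f"({self.amplicon_length_target} bp)"
            )
        return n


def default_primer_pairs() -> Dict[str, PrimerPair]:
    """The three stock primer pairs: 16S V4 (515F/806R), 18S (F1427/R1616)
    and fungal ITS (ITS1F/ITS2R), with their standard read-length windows.

    Amplicon targets are the window centres (253, 211) and the modal ITS
    amplicon size (272)."""
    return {
        "P": PrimerPair("P", "GTGCCAGCMGCCGCGGTAA", "GGACTACHVGGGTWTCTAAT",
                        253, (252, 254)),
        "E": PrimerPair("E", "TCTGTGATGCCCTTAGATGTTCTGGG",
                        "GCGGTGTGTACAAAGGGCAGGG", 211, (210, 212)),
        "F": PrimerPair("F", "CTTGGTCATTTAGAGGAAGTAA", "GCTGCGTTCTTCATCGATGC",
                        272, (250, 300)),
    }


# ---------------------------------------------------------------------------
# IUPAC-aware motif search


def _matches_at(pattern: str, window: str, budget: int) -> bool:
    # both sides may carry ambiguity codes: mismatch = disjoint base sets
    n = 0
    for p, b in zip(pattern, window):
        if IUPAC_SETS[p].isdisjoint(IUPAC_SETS[b]):
            n += 1
            if n > budget:
                return False
    return True


def find_motif(template: str, motif: str, max_mismatches: int = 0) -> List[int]:
    """Start positions where ``motif`` occurs in ``template`` with at most
    ``max_mismatches`` substitutions.  IUPAC codes in ``motif`` match their
    base sets; template bases are taken literally."""
    template = template.upper()
    motif = motif.upper()
    k = len(motif)
    if k == 0 or k > len(template):
        return []
    return [
        i
        for i in range(len(template) - k + 1)
        if _matches_at(motif, template[i : i + k], max_mismatches)
    ]


# ---------------------------------------------------------------------------
# Stuffer generation


def generate_stuffer(
    length_bp: int,
    gc_target: float,
    gc_tolerance: float,
    forbidden_motifs: Sequence[str] = (),
    seed: int = 0,
    *,
    max_mismatches: int = 0,
    homopolymer_cap: int | None = 8,
    max_attempts: int = 10_000,
) -> str:
    """Draw a random stuffer of exact length with GC within tolerance.

    The GC count is drawn uniformly from the integer band allowed by the
    tolerance and bases shuffled, so the composition constraint holds by
    construction; motif and homopolymer constraints are enforced by
    rejection.  ``forbidden_motifs`` are screened in both orientations at
    Hamming distance <= ``max_mismatches``.  Deterministic for a fixed seed.

    Raises ``RuntimeError`` when no valid sequence is found within
    ``max_attempts`` (over-constrained input).
    """
    if length_bp < 0:
        raise ValueError("length_bp must be >= 0")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must lie in [0, 1]")
    if gc_tolerance < 0:
        raise ValueError("gc_tolerance must be >= 0")
    if length_bp == 0:
        return ""

    lo = max(0, math.ceil((gc_target - gc_tolerance) * length_bp - 1e-9))
    hi = min(length_bp, math.floor((gc_target + gc_tolerance) * length_bp + 1e-9))
    if lo > hi:
        raise ValueError(
            f"no integer GC count in [{gc_target - gc_tolerance}, "
            f"{gc_target + gc_tolerance}] for length {length_bp}"
        )

    motifs: List[str] = []
    for m in forbidden_motifs:
        m = m.upper()
        _check_dna(m, "forbidden motif")
        motifs.append(m)
        motifs.append(revcomp(m))

    homopoly = (
        re.compile(r"(.)\1{%d,}" % homopolymer_cap)
        if homopolymer_cap is not None
        else None
    )

    rng = np.random.default_rng(seed)
    gc_pool = np.array(["G", "C"])
    at_pool = np.array(["A", "T"])
    for _ in range(max_attempts):
        n_gc = int(rng.integers(lo, hi + 1))
        arr = np.concatenate(
            [rng.choice(gc_pool, n_gc), rng.choice(at_pool, length_bp - n_gc)]
        )
        rng.shuffle(arr)
        seq = "".join(arr)
        if homopoly is not None and homopoly.search(seq):
            continue
        if any(find_motif(seq, m, max_mismatches) for m in motifs):
            continue
        return seq
    raise RuntimeError(
        f"no stuffer satisfying the constraints found in {max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# Spike assembly and validation


@dataclass(frozen=True)
class SpikeSpec:
    """A designed chimeric spike: PBSs flanking a synthetic stuffer.

    ``construct_length_bp`` is the full delivered molecule (e.g. plasmid
    backbone plus insert) used for first-principles mass-to-copies
    conversion when no measured stock value is available.
    """

    family: str
    primer_pair: PrimerPair
    stuffer: str
    gc_target: float = 0.5
    gc_tolerance: float = 0.02
    construct_length_bp: int | None = None

    @property
    def amplicon(self) -> str:
        return assemble_spike(self.primer_pair, self.stuffer)

    @property
    def gc(self) -> float:
        return gc_fraction(self.stuffer) if self.stuffer else 0.0


def assemble_spike(primer_pair: PrimerPair, stuffer: str) -> str:
    """Amplicon sequence = forward PBS + stuffer + revcomp(reverse PBS).

    An on-target stuffer has exactly ``primer_pair.stuffer_length`` bases
    (accessing that property raises when the primers alone exceed the
    amplicon target); off-length stuffers still assemble so that defective
    constructs can be represented and caught by :func:`validate_spike`.
    """
    _check_dna(stuffer, "stuffer")
    primer_pair.stuffer_length  # raises on negative implied length
    return primer_pair.forward + stuffer + revcomp(primer_pair.reverse)


def design_spike(
    family: str,
    primer_pair: PrimerPair,
    all_primers: Iterable[PrimerPair] = (),
    *,
    gc_target: float = 0.5,
    gc_tolerance: float = 0.02,
    seed: int = 0,
    pbs_mismatch_budget: int = 2,
    homopolymer_cap: int = 8,
    construct_length_bp: int | None = None,
) -> SpikeSpec:
    """Design one spike: a stuffer free of every PBS in the experiment
    (own pair included, both orientations, Hamming <= budget)."""
    primers = list(all_primers)
    if primer_pair not in primers:
        primers.append(primer_pair)
    forbidden = [p.forward for p in primers] + [p.reverse for p in primers]
    stuffer = generate_stuffer(
        primer_pair.stuffer_length,
        gc_target,
        gc_tolerance,
        forbidden,
        seed,
        max_mismatches=pbs_mismatch_budget,
        homopolymer_cap=homopolymer_cap,
    )
    return SpikeSpec(family, primer_pair, stuffer, gc_target, gc_tolerance,
                     construct_length_bp)


def default_spikes(seed: int = 7) -> Dict[str, SpikeSpec]:
    """One spike per stock primer pair, cross-screened against all three
    pairs.  Construct length defaults to 2504 bp (a typical cloning-vector
    backbone plus insert, consistent with stocks near 3.7e8 copies/ng)."""
    pairs = default_primer_pairs()
    return {
        fam: design_spike(
            fam, pair, pairs.values(), seed=seed + i, construct_length_bp=2504
        )
        for i, (fam, pair) in enumerate(sorted(pairs.items()))
    }


def in_silico_pcr(
    template: str,
    primer_pair: PrimerPair,
    max_mismatches: int = 1,
    max_product_bp: int = 5000,
) -> List[Tuple[int, int, int]]:
    """All products (start, end, length) delimited by a forward-primer match
    and a downstream reverse-primer reverse-complement match.

    Products longer than ``max_product_bp`` or shorter than the longest
    primer are not reported.  Empty template raises; no match returns []."""
    if not template:
        raise ValueError("template must be non-empty")
    template = template.upper()
    fwd_starts = find_motif(template, primer_pair.forward, max_mismatches)
    rev_rc = revcomp(primer_pair.reverse)
    rev_starts = find_motif(template, rev_rc, max_mismatches)
    min_len = max(len(primer_pair.forward), len(rev_rc))
    products = []
    for f in fwd_starts:
        for r in rev_starts:
            end = r + len(rev_rc)
            length = end - f
            if r >= f and min_len <= length <= max_product_bp:
                products.append((f, end, length))
    return sorted(products)


@dataclass
class ValidationReport:
    """Pass/fail per design constraint; ``passed`` is the conjunction."""

    checks: Dict[str, bool] = field(default_factory=dict)
    details: Dict[str, str] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        lines = [
            f"[{'ok' if ok else 'FAIL'}] {name}: {self.details.get(name, '')}"
            for name, ok in self.checks.items()
        ]
        return "\n".join(lines)


def validate_spike(
    spike: SpikeSpec,
    all_primers: Iterable[PrimerPair] = (),
    *,
    pbs_mismatch_budget: int = 2,
    homopolymer_cap: int = 8,
) -> ValidationReport:
    """Check a spike against the design constraints: amplicon length within
    the family window, stuffer GC within tolerance, no PBS of any supplied
    primer pair inside the stuffer, and no over-long homopolymer."""
    report = ValidationReport()
    amplicon = spike.amplicon
    lo, hi = spike.primer_pair.amplicon_length_window
    ok = lo <= len(amplicon) <= hi
    report.checks["length_in_window"] = ok
    report.details["length_in_window"] = f"{len(amplicon)} bp vs [{lo}, {hi}]"

    gc = spike.gc
    ok = abs(gc - spike.gc_target) <= spike.gc_tolerance + 1e-12
    report.checks["gc_within_tolerance"] = ok
    report.details["gc_within_tolerance"] = (
        f"GC {gc:.3f} vs {spike.gc_target} +/- {spike.gc_tolerance}"
    )

    primers = list(all_primers)
    if spike.primer_pair not in primers:
        primers.append(spike.primer_pair)
    hits = []
    for pair in primers:
        for motif in (pair.forward, pair.reverse):
            for m in (motif, revcomp(motif)):
                if find_motif(spike.stuffer, m, pbs_mismatch_budget):
                    hits.append(pair.name)
    report.checks["no_pbs_in_stuffer"] = not hits
    report.details["no_pbs_in_stuffer"] = (
        f"PBS hits from pairs: {sorted(set(hits))}" if hits else "clean"
    )

    homopoly = re.search(r"(.)\1{%d,}" % homopolymer_cap, spike.stuffer)
    report.checks["homopolymer_ok"] = homopoly is None
    report.details["homopolymer_ok"] = (
        f"run of {len(homopoly.group(0))} at {homopoly.start()}"
        if homopoly
        else f"no run > {homopolymer_cap}"
    )
    return report


# ---------------------------------------------------------------------------
# FASTA I/O


def write_spikes_fasta(spikes: Iterable[SpikeSpec], path) -> None:
    records = []
    for s in spikes:
        records.append(
            SeqRecord(
                Seq(s.amplicon),
                id=f"spike_{s.family}",
                description=(
                    f"family={s.family} length={len(s.amplicon)} gc={s.gc:.3f}"
                ),
            )
        )
    SeqIO.write(records, str(path), "fasta")


def read_spikes_fasta(path, primer_pairs: Dict[str, PrimerPair]) -> Dict[str, SpikeSpec]:
    """Load spike amplicons written by :func:`write_spikes_fasta`, recovering
    the stuffer by trimming the family's PBSs."""
    spikes: Dict[str, SpikeSpec] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(
            kv.split("=") for kv in rec.description.split() if "=" in kv
        )
        family = fields.get("family", rec.id.removeprefix("spike_"))
        pair = primer_pairs[family]
        seq = str(rec.seq).upper()
        stuffer = seq[len(pair.forward) : len(seq) - len(pair.reverse)]
        spikes[family] = SpikeSpec(family, pair, stuffer)
    return spikes
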