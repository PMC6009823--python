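"""Simulated spiked amplicon experiments with known ground truth.

The generator emulates the reference study design: a soil-like community
with lognormally dispersed taxon abundances totalling about 1e9 16S, 1e8
18S and 1e7 ITS gene copies per gram; synthetic spikes dosed from the
default level table; optional DNA-isolation loss (which cancels when
spikes are added before isolation and does not when added after); and
multinomial sequencing at configurable depth, optionally emitted as
barcoded FASTQ reads for the full read-processing pipeline.

Everything downstream is testable against the latent truth: the multinomial
draw, the per-family totals, and constructed scenarios such as a taxon
whose relative abundance falls while its absolute abundance rises.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import planner
from .copy_number import default_level_table
from .read_processing import (
    CountTable,
    DemuxScheme,
    ReadRecord,
    Reference,
    synthetic_category,
)
from .spike_design import (
    IUPAC_SETS,
    PrimerPair,
    SpikeSpec,
    default_primer_pairs,
    default_spikes,
    generate_stuffer,
    revcomp,
)

#: study-condition family totals, gene copies per gram of soil
FAMILY_TOTALS = {"P": 1e9, "E": 1e8, "F": 1e7}
#: lognormal dispersion (natural-log SD) of taxon abundances
DEFAULT_DISPERSION = 1.5
DEFAULT_N_TAXA = {"P": 30, "E": 20, "F": 12}

_PAD_FORWARD = "ACACGACGCTCT"
_PAD_REVERSE = "GTGACTGGAGTT"
_BARCODE_LEN = 8


@dataclass
class TruthRecord:
    """Ground truth for one simulated sample/community.

    ``taxa`` maps family -> per-taxon gene copies per gram (a Series whose
    sum is the family total); ``spike_copies`` the dose per family.
    """

    taxa: Dict[str, pd.Series]
    spike_copies: Dict[str, float]
    isolation_efficiency: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.isolation_efficiency <= 1:
            raise ValueError("isolation efficiency must lie in (0, 1]")

    def family_total(self, family: str) -> float:
        return float(self.taxa[family].sum())


def make_community(
    n_taxa: int | Dict[str, int] | None = None,
    family_totals: Dict[str, float] | None = None,
    dispersion: float = DEFAULT_DISPERSION,
    seed: int = 0,
    spike_copies: Dict[str, float] | None = None,
    isolation_efficiency: float = 1.0,
) -> TruthRecord:
    """Draw a community: per family, taxon proportions are lognormal(0,
    dispersion) normalised and scaled to the family total.

    ``dispersion=0`` gives equal proportions.  When ``spike_copies`` is not
    given, each family's dose is the first in-window level of the default
    dose table for the family's own total (i.e. a well-planned experiment).
    """
    family_totals = dict(family_totals or FAMILY_TOTALS)
    if any(t <= 0 for t in family_totals.values()):
        raise ValueError("family totals must be > 0")
    if n_taxa is None:
        n_map = {f: DEFAULT_N_TAXA.get(f, 20) for f in family_totals}
    elif isinstance(n_taxa, int):
        n_map = {f: n_taxa for f in family_totals}
    else:
        n_map = dict(n_taxa)
    rng = np.random.default_rng(seed)
    taxa: Dict[str, pd.Series] = {}
    for fam in sorted(family_totals):
        n = n_map[fam]
        if n < 1:
            raise ValueError("n_taxa must be >= 1")
        props = np.exp(rng.normal(0.0, dispersion, size=n))
        props /= props.sum()
        labels = [f"{fam}_taxon{i:02d}" for i in range(n)]
        taxa[fam] = pd.Series(props * family_totals[fam], index=labels)
    if spike_copies is None:
        spike_copies = plan_default_doses(family_totals)
    return TruthRecord(taxa, dict(spike_copies), isolation_efficiency, seed)


def plan_default_doses(family_totals: Dict[str, float]) -> Dict[str, float]:
    """First in-window spike level per family for the given totals."""
    table = default_level_table()
    doses: Dict[str, float] = {}
    for fam, env in family_totals.items():
        ann = planner.select_levels(table[table["family"] == fam], env)
        ok = ann[ann["in_window"]]
        if ok.empty:
            raise ValueError(f"no in-window spike level for family {fam}")
        doses[fam] = float(ok.iloc[0]["copies"])
    return doses


def sequence_sample(
    truth: TruthRecord,
    depth: int,
    seed: int = 0,
    sample: str = "S1",
    spike_timing: str = "before",
) -> CountTable:
    """One multinomial sequencing draw per family at the given depth.

    Read probabilities are proportional to isolation-efficiency-scaled
    taxon copies plus spike copies; spikes are scaled too only when added
    before isolation (``spike_timing="before"``), which is why the
    efficiency cancels in that mode and not in the other.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if spike_timing not in ("before", "after"):
        raise ValueError("spike_timing must be 'before' or 'after'")
    rng = np.random.default_rng(seed)
    frames = []
    fams = []
    for fam in sorted(truth.taxa):
        counts = _draw_family_counts(truth, fam, depth, rng, spike_timing)
        frames.append(counts)
        fams.extend([fam] * len(counts))
    col = pd.concat(frames)
    counts_df = col.to_frame(sample)
    return CountTable(counts_df, pd.Series(fams, index=counts_df.index))


def _draw_family_counts(
    truth: TruthRecord,
    family: str,
    depth: int,
    rng: np.random.Generator,
    spike_timing: str,
) -> pd.Series:
    eff = truth.isolation_efficiency
    taxa = truth.taxa[family] * eff
    spike = truth.spike_copies[family] * (eff if spike_timing == "before" else 1.0)
    pool = np.concatenate([taxa.to_numpy(), [spike]])
    p = pool / pool.sum()
    draw = rng.multinomial(depth, p)
    index = list(taxa.index) + [synthetic_category(family)]
    return pd.Series(draw, index=index)


# ---------------------------------------------------------------------------
# Full FASTQ-level runs


def _realise(seq: str, rng: np.random.Generator) -> str:
    """Replace IUPAC ambiguity codes by concrete bases."""
    out = []
    for ch in seq:
        opts = sorted(IUPAC_SETS[ch])
        out.append(opts[0] if len(opts) == 1 else opts[rng.integers(len(opts))])
    return "".join(out)


def make_references(
    primer_pairs: Dict[str, PrimerPair],
    n_taxa: Dict[str, int],
    seed: int = 0,
) -> List[Reference]:
    """Synthetic reference amplicons, one per taxon, with realised PBSs and
    random inserts (variable length for ITS, fixed for 16S/18S)."""
    rng = np.random.default_rng(seed)
    refs: List[Reference] = []
    for fam in sorted(n_taxa):
        pair = primer_pairs[fam]
        lo, hi = pair.amplicon_length_window
        for i in range(n_taxa[fam]):
            if hi - lo > 4:  # length-variable family: sample inside the window
                amp_len = int(rng.integers(lo + 2, hi - 1))
            else:
                amp_len = pair.amplicon_length_target
            insert_len = amp_len - len(pair.forward) - len(pair.reverse)
            insert = generate_stuffer(
                insert_len, 0.5, 0.08, seed=int(rng.integers(2**31)),
                homopolymer_cap=None,
            )
            amplicon = (
                _realise(pair.forward, rng) + insert + revcomp(_realise(pair.reverse, rng))
            )
            label = f"{fam}_taxon{i:02d}"
            refs.append(Reference(label, fam, amplicon, f"sim;{fam};clade{i:02d}"))
    return refs


def _make_scheme(n_samples: int, rng: np.random.Generator) -> DemuxScheme:
    bases = np.array(list("ACGT"))
    barcodes = set()
    pairs: Dict[Tuple[str, str], str] = {}
    for i in range(n_samples):
        while True:
            f = "".join(rng.choice(bases, _BARCODE_LEN))
            r = "".join(rng.choice(bases, _BARCODE_LEN))
            if (f, r) not in pairs and f not in barcodes and r not in barcodes:
                barcodes.update((f, r))
                break
        pairs[(f, r)] = f"S{i + 1:02d}"
    return DemuxScheme(_PAD_FORWARD, _PAD_REVERSE, pairs)


@dataclass
class SimulatedRun:
    """A complete simulated sequencing run plus its latent truth."""

    reads: List[ReadRecord]
    scheme: DemuxScheme
    primer_pairs: Dict[str, PrimerPair]
    spikes: Dict[str, SpikeSpec]
    references: List[Reference]
    truth_counts: CountTable
    manifest: pd.DataFrame
    truths: Dict[str, TruthRecord] = field(default_factory=dict)
    planted_off_length: Dict[str, int] = field(default_factory=dict)


def simulate_run(
    n_samples: int = 6,
    depth_per_family: int = 20_000,
    seed: int = 0,
    families: Tuple[str, ...] = ("P", "E", "F"),
    error_rate: float = 0.0,
    off_length_fraction: float = 0.0,
    n_groups: int = 2,
    dispersion: float = DEFAULT_DISPERSION,
) -> SimulatedRun:
    """Simulate a multi-sample, multi-family spiked run down to reads.

    Samples are split over ``n_groups`` soil-like groups with independent
    communities (the later groups scaled up 2x per step, emulating a richer
    soil).  Per (sample, family) a multinomial draw of
    ``depth_per_family`` reads is made and emitted as barcoded, padded,
    primer-flanked reads; ``truth_counts`` holds exactly that latent draw,
    so error-free processing must reproduce it read for read.

    ``off_length_fraction`` replaces that fraction of reads by an
    out-of-window length variant (still counted in ``truth_counts``);
    ``error_rate`` adds i.i.d. substitutions per base.
    """
    rng = np.random.default_rng(seed)
    primer_pairs = {f: p for f, p in default_primer_pairs().items() if f in families}
    spikes = {f: s for f, s in default_spikes(seed=7).items() if f in families}
    totals = {f: FAMILY_TOTALS[f] for f in families}
    n_taxa = {f: DEFAULT_N_TAXA[f] for f in families}
    references = make_references(primer_pairs, n_taxa, seed=int(rng.integers(2**31)))
    refs_by_label = {r.label: r for r in references}
    scheme = _make_scheme(n_samples, rng)
    doses = plan_default_doses(totals)

    group_truths: List[TruthRecord] = []
    for g in range(n_groups):
        scale = 2.0**g
        truth = make_community(
            n_taxa,
            {f: t * scale for f, t in totals.items()},
            dispersion=dispersion,
            seed=int(rng.integers(2**31)),
            spike_copies=doses,
        )
        group_truths.append(truth)

    # off-length variants share the insert prefix but break the window
    off_variants: Dict[str, str] = {}
    for label, ref in refs_by_label.items():
        pair = primer_pairs[ref.family]
        lo, hi = pair.amplicon_length_window
        pad_len = hi + 7 - len(ref.amplicon)
        extra = generate_stuffer(
            pad_len, 0.5, 0.25, seed=int(rng.integers(2**31)), homopolymer_cap=None
        )
        off_variants[label] = ref.amplicon[: len(ref.amplicon) - len(pair.reverse)] \
            + extra + ref.amplicon[len(ref.amplicon) - len(pair.reverse):]

    # sequenced spike molecules are concrete: realise PBS ambiguity codes
    spike_amplicons = {
        fam: _realise(spike.amplicon, rng) for fam, spike in sorted(spikes.items())
    }

    bc_of_sample = {s: pair for pair, s in scheme.barcode_map.items()}
    reads: List[ReadRecord] = []
    truth_cols: Dict[str, pd.Series] = {}
    manifest_rows = []
    truths: Dict[str, TruthRecord] = {}
    planted: Dict[str, int] = {f: 0 for f in families}
    read_idx = 0
    for i, sample in enumerate(scheme.samples):
        group = i % n_groups
        truth = group_truths[group]
        truths[sample] = truth
        table = sequence_sample(
            truth, depth_per_family, seed=int(rng.integers(2**31)), sample=sample
        )
        truth_cols[sample] = table.counts[sample]
        fbc, rbc = bc_of_sample[sample]
        prefix = fbc + _PAD_FORWARD
        suffix = revcomp(_PAD_REVERSE) + revcomp(rbc)
        for category, count in table.counts[sample].items():
            if count == 0:
                continue
            fam = table.family[category]
            if category == synthetic_category(fam):
                amplicon = spike_amplicons[fam]
                off_amp = None
            else:
                amplicon = refs_by_label[category].amplicon
                off_amp = off_variants[category]
            n_off = (
                rng.binomial(count, off_length_fraction)
                if off_length_fraction > 0 and off_amp is not None
                else 0
            )
            planted[fam] += n_off
            for variant, n in ((amplicon, count - n_off), (off_amp, n_off)):
                for _ in range(n):
                    seq = prefix + variant + suffix
                    if error_rate > 0:
                        seq = _mutate(seq, error_rate, rng)
                    reads.append(ReadRecord(f"read_{read_idx:07d}", seq))
                    read_idx += 1
        for fam in sorted(families):
            manifest_rows.append(
                {
                    "sample": sample,
                    "family": fam,
                    "group": f"group{group}",
                    "spike_copies": doses[fam],
                    "amount": 1.0,
                    "unit": "g",
                    "spike_timing": "before",
                    "contaminated": False,
                }
            )

    truth_df = pd.DataFrame(truth_cols)
    fam_series = pd.Series(
        {
            cat: (
                cat.removeprefix("synthetic_")
                if cat.startswith("synthetic_")
                else refs_by_label[cat].family
            )
            for cat in truth_df.index
        }
    )
    truth_counts = CountTable(truth_df, fam_series.loc[truth_df.index])
    manifest = pd.DataFrame(manifest_rows)
    return SimulatedRun(
        reads, scheme, primer_pairs, spikes, references, truth_counts,
        manifest, truths, planted,
    )


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    positions = rng.choice(len(seq), size=n, replace=False)
    arr = list(seq)
    for pos in positions:
        choices = [b for b in "ACGT" if b != arr[pos]]
        arr[pos] = choices[rng.integers(3)]
    return "".join(arr)


# ---------------------------------------------------------------------------
# The relative-down / absolute-up scenario


@dataclass
class Scenario:
    """Two sample groups where one taxon's absolute abundance rises from A
    to B while its relative abundance falls (other taxa inflated more)."""

    count_table: CountTable
    manifest: pd.DataFrame
    truth_a: pd.Series
    truth_b: pd.Series
    designated: str
    family: str
    spike_copies: float


def scenario_relative_vs_absolute(
    seed: int = 0,
    n_per_group: int = 10,
    n_taxa: int = 12,
    depth: int = 100_000,
    replicate_sigma: float = 0.05,
    family: str = "P",
    designated_factor: float = 1.5,
    background_factor: float = 3.0,
    spike_copies: float = 2e9,
) -> Scenario:
    """Construct the sign-flip scenario and sequence both groups.

    Group B multiplies the designated taxon's copies by
    ``designated_factor`` and every other taxon by the larger
    ``background_factor``, so in truth the designated taxon is absolutely
    up but relatively down.  Per-sample replicate variability is lognormal
    with SD ``replicate_sigma`` on the natural-log scale.  Raises for a
    single-taxon community, where the construction is impossible.
    """
    if n_taxa < 2:
        raise ValueError("scenario needs >= 2 taxa")
    if not designated_factor > 1:
        raise ValueError("designated_factor must exceed 1")
    if not background_factor > designated_factor:
        raise ValueError("background_factor must exceed designated_factor")
    rng = np.random.default_rng(seed)
    base = make_community(
        {family: n_taxa}, {family: FAMILY_TOTALS[family]},
        seed=int(rng.integers(2**31)),
        spike_copies={family: spike_copies},
    )
    truth_a = base.taxa[family]
    designated = truth_a.idxmax()  # well-covered taxon
    factors = pd.Series(background_factor, index=truth_a.index)
    factors[designated] = designated_factor
    truth_b = truth_a * factors

    cols: Dict[str, pd.Series] = {}
    manifest_rows = []
    for label, truth_taxa in (("A", truth_a), ("B", truth_b)):
        for i in range(n_per_group):
            sample = f"{label}{i + 1:02d}"
            jitter = np.exp(rng.normal(0.0, replicate_sigma, size=n_taxa))
            record = TruthRecord(
                {family: truth_taxa * jitter}, {family: spike_copies}
            )
            table = sequence_sample(
                record, depth, seed=int(rng.integers(2**31)), sample=sample
            )
            cols[sample] = table.counts[sample]
            manifest_rows.append(
                {
                    "sample": sample,
                    "family": family,
                    "group": label,
                    "spike_copies": spike_copies,
                    "amount": 1.0,
                    "unit": "g",
                    "spike_timing": "before",
                    "contaminated": False,
                }
            )
    df = pd.DataFrame(cols)
    fam_series = pd.Series(family, index=df.index)
    return Scenario(
        CountTable(df, fam_series),
        pd.DataFrame(manifest_rows),
        truth_a,
        truth_b,
        designated,
        family,
        spike_copies,
    )
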