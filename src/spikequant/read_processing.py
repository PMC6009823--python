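"""From raw spiked amplicon reads to a sample x category count table.

Reads are merged single-end amplicons laid out as

    [fwd barcode][fwd pad][amplicon][revcomp(rev pad)][revcomp(rev barcode)]

where the amplicon is forward PBS + insert + revcomp(reverse PBS).
Processing proceeds demultiplex -> family assignment -> length filter ->
classification.  Classification is nearest-neighbour by Hamming distance
against spike and taxon reference sequences; denoising is deliberately not
re-implemented — a pre-made count table can be supplied instead via
:meth:`CountTable.from_tsv`.

Read counts are conserved at every stage: every input read ends in exactly
one (sample, category) cell or in the unassigned report.
"""

from __future__ import annotations

import gzip
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Tuple

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .spike_design import PrimerPair, SpikeSpec, _matches_at, revcomp

SYNTHETIC_PREFIX = "synthetic_"


def synthetic_category(family: str) -> str:
    return SYNTHETIC_PREFIX + family


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read (merged amplicon)."""

    identifier: str
    sequence: str
    quality: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("read sequence must be non-empty")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length must match sequence length")


@dataclass(frozen=True)
class Reference:
    """A labelled reference amplicon with its taxonomic lineage."""

    label: str
    family: str
    amplicon: str
    lineage: str = ""


class DemuxScheme:
    """Dual-barcode demultiplexing scheme with fixed amplification pads."""

    def __init__(
        self,
        pad_forward: str,
        pad_reverse: str,
        barcode_map: Dict[Tuple[str, str], str],
    ) -> None:
        if not barcode_map:
            raise ValueError("barcode_map must be non-empty")
        lengths = {len(b) for pair in barcode_map for b in pair}
        if len(lengths) != 1:
            raise ValueError("all barcodes must have equal length")
        samples = list(barcode_map.values())
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample identifiers in barcode map")
        self.pad_forward = pad_forward.upper()
        self.pad_reverse = pad_reverse.upper()
        self.barcode_map = {
            (f.upper(), r.upper()): s for (f, r), s in barcode_map.items()
        }
        self.barcode_length = lengths.pop()

    @property
    def samples(self) -> List[str]:
        return list(self.barcode_map.values())

    def to_tsv(self, path) -> None:
        rows = [
            {
                "sample": s,
                "barcode_forward": f,
                "barcode_reverse": r,
                "pad_forward": self.pad_forward,
                "pad_reverse": self.pad_reverse,
            }
            for (f, r), s in self.barcode_map.items()
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "DemuxScheme":
        df = pd.read_csv(path, sep="\t", dtype=str)
        pairs = list(zip(df["barcode_forward"], df["barcode_reverse"]))
        if len(set(pairs)) != len(pairs):
            raise ValueError(f"duplicate barcode pairs in {path}")
        return cls(
            df["pad_forward"].iloc[0],
            df["pad_reverse"].iloc[0],
            dict(zip(pairs, df["sample"])),
        )


# ---------------------------------------------------------------------------
# FASTQ I/O


def read_fastq(path) -> Iterator[ReadRecord]:
    """Stream a FASTQ file (plain or gzip) as ReadRecords."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "rt") as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield ReadRecord(title.split()[0], seq.upper(), qual)


def write_fastq(reads: Iterable[ReadRecord], path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as handle:
        for r in reads:
            qual = r.quality if r.quality is not None else "I" * len(r.sequence)
            handle.write(f"@{r.identifier}\n{r.sequence}\n+\n{qual}\n")


def read_references_fasta(
    path, primer_pairs: Dict[str, PrimerPair], max_mismatches: int = 1
) -> List[Reference]:
    """Load references from FASTA with ``>label;tax=<lineage>`` headers;
    the family of each record is inferred from its PBSs."""
    from Bio import SeqIO

    refs = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description
        label = header.split(";")[0].split()[0]
        lineage = ""
        for part in header.split(";")[1:]:
            if part.strip().startswith("tax="):
                lineage = part.strip()[len("tax="):]
        seq = str(rec.seq).upper()
        fam, _ = assign_family_seq(seq, primer_pairs.values(), max_mismatches)
        if fam is None:
            raise ValueError(f"reference {label} matches no primer pair")
        refs.append(Reference(label, fam, seq, lineage))
    return refs


def write_references_fasta(refs: Iterable[Reference], path) -> None:
    with open(str(path), "w") as fh:
        for r in refs:
            fh.write(f">{r.label};tax={r.lineage}\n{r.amplicon}\n")


# ---------------------------------------------------------------------------
# Demultiplexing


def _hamming_le(a: str, b: str, budget: int) -> bool:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > budget:
                return False
    return True


def demultiplex(
    reads: Iterable[ReadRecord],
    scheme: DemuxScheme,
    max_mismatches: int = 0,
) -> Tuple[Dict[str, List[ReadRecord]], List[ReadRecord]]:
    """Bin reads by dual barcode and trim barcodes + pads.

    Every read lands in exactly one sample bin (trimmed to the amplicon) or
    in the unassigned list, so counts are conserved.  With a non-zero
    mismatch budget an ambiguous barcode pair is unassigned.
    """
    bins: Dict[str, List[ReadRecord]] = {s: [] for s in scheme.samples}
    unassigned: List[ReadRecord] = []
    for read in reads:
        sample, amplicon, qual = _demux_one(read, scheme, max_mismatches)
        if sample is None:
            unassigned.append(read)
        else:
            bins[sample].append(ReadRecord(read.identifier, amplicon, qual))
    return bins, unassigned


def _demux_one(
    read: ReadRecord, scheme: DemuxScheme, max_mismatches: int
) -> Tuple[Optional[str], str, Optional[str]]:
    bl = scheme.barcode_length
    pl_f = len(scheme.pad_forward)
    pl_r = len(scheme.pad_reverse)
    seq = read.sequence
    if len(seq) < 2 * bl + pl_f + pl_r + 1:
        return None, seq, read.quality
    fbc = seq[:bl]
    rbc = revcomp(seq[-bl:])
    if max_mismatches == 0:
        sample = scheme.barcode_map.get((fbc, rbc))
    else:
        hits = [
            s
            for (f, r), s in scheme.barcode_map.items()
            if _hamming_le(fbc, f, max_mismatches)
            and _hamming_le(rbc, r, max_mismatches)
        ]
        sample = hits[0] if len(hits) == 1 else None
    if sample is None:
        return None, seq, read.quality
    if not _hamming_le(seq[bl : bl + pl_f], scheme.pad_forward, max_mismatches):
        return None, seq, read.quality
    if not _hamming_le(
        seq[len(seq) - bl - pl_r : len(seq) - bl],
        revcomp(scheme.pad_reverse),
        max_mismatches,
    ):
        return None, seq, read.quality
    start, stop = bl + pl_f, len(seq) - bl - pl_r
    qual = read.quality[start:stop] if read.quality is not None else None
    return sample, seq[start:stop], qual


# ---------------------------------------------------------------------------
# Family assignment and length filtering


def assign_family_seq(
    sequence: str,
    primer_pairs: Iterable[PrimerPair],
    max_mismatches: int = 1,
) -> Tuple[Optional[str], str]:
    """Assign an amplicon to the family whose forward PBS matches at the 5'
    end and reverse PBS (reverse complement) at the 3' end, within the
    mismatch budget.  Returns (family or None, PBS-trimmed insert).

    When several pairs match, the one with fewest total mismatches wins;
    remaining ties break to the lexicographically first family name.
    """
    sequence = sequence.upper()
    candidates: List[Tuple[int, str, str]] = []
    for pair in primer_pairs:
        f = pair.forward
        r_rc = revcomp(pair.reverse)
        if len(sequence) < len(f) + len(r_rc):
            continue
        head = sequence[: len(f)]
        tail = sequence[len(sequence) - len(r_rc):]
        mm = _iupac_mismatches(f, head, max_mismatches)
        if mm is None:
            continue
        mm_r = _iupac_mismatches(r_rc, tail, max_mismatches)
        if mm_r is None:
            continue
        insert = sequence[len(f) : len(sequence) - len(r_rc)]
        candidates.append((mm + mm_r, pair.name, insert))
    if not candidates:
        return None, sequence
    candidates.sort(key=lambda c: (c[0], c[1]))
    _, family, insert = candidates[0]
    return family, insert


def _iupac_mismatches(pattern: str, window: str, budget: int) -> Optional[int]:
    from .spike_design import IUPAC_SETS

    # template may itself carry ambiguity codes (e.g. designed amplicons)
    n = 0
    for p, b in zip(pattern, window):
        if IUPAC_SETS[p].isdisjoint(IUPAC_SETS[b]):
            n += 1
            if n > budget:
                return None
    return n


def assign_family(
    read: ReadRecord,
    primer_pairs: Iterable[PrimerPair],
    max_mismatches: int = 1,
) -> Tuple[Optional[str], ReadRecord]:
    """ReadRecord wrapper around :func:`assign_family_seq`; quality is
    trimmed alongside the sequence."""
    primer_pairs = list(primer_pairs)
    fam, insert = assign_family_seq(read.sequence, primer_pairs, max_mismatches)
    if fam is None:
        return None, read
    pair = {p.name: p for p in primer_pairs}[fam]
    start = len(pair.forward)
    stop = len(read.sequence) - len(pair.reverse)
    qual = read.quality[start:stop] if read.quality is not None else None
    return fam, ReadRecord(read.identifier, insert, qual)


def length_filter(
    reads_by_family: Dict[str, List[ReadRecord]],
    windows: Dict[str, Tuple[int, int]],
) -> Tuple[Dict[str, List[ReadRecord]], Dict[str, float]]:
    """Retain reads whose PBS-inclusive amplicon length falls in the
    family's inclusive window; report the per-family retention fraction.

    Input reads must still carry the full amplicon (before PBS trimming),
    since read-length filtering applies to sequenced amplicon lengths.
    """
    retained: Dict[str, List[ReadRecord]] = {}
    fractions: Dict[str, float] = {}
    for fam, reads in reads_by_family.items():
        if fam not in windows:
            raise KeyError(f"no length window for family {fam}")
        lo, hi = windows[fam]
        kept = [r for r in reads if lo <= len(r.sequence) <= hi]
        retained[fam] = kept
        fractions[fam] = len(kept) / len(reads) if reads else float("nan")
    return retained, fractions


# ---------------------------------------------------------------------------
# Count table


@dataclass
class CountTable:
    """Samples x categories read counts; categories are taxon labels plus
    one synthetic category per amplicon family.

    ``counts`` is categories (rows) x samples (columns); ``family`` maps
    each category to its amplicon family.
    """

    counts: pd.DataFrame
    family: pd.Series

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.equals(self.family.index):
            self.family = self.family.reindex(self.counts.index)
            if self.family.isna().any():
                raise ValueError("every category needs a family tag")

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    @property
    def categories(self) -> List[str]:
        return list(self.counts.index)

    def families(self) -> List[str]:
        return sorted(self.family.unique())

    def is_synthetic(self) -> pd.Series:
        return pd.Series(
            [c.startswith(SYNTHETIC_PREFIX) for c in self.counts.index],
            index=self.counts.index,
        )

    def family_slice(self, family: str) -> pd.DataFrame:
        return self.counts.loc[self.family == family]

    def total_reads(self, sample: str, family: str) -> int:
        return int(self.family_slice(family)[sample].sum())

    def synthetic_reads(self, sample: str, family: str) -> int:
        cat = synthetic_category(family)
        if cat not in self.counts.index:
            return 0
        return int(self.counts.loc[cat, sample])

    def microbial_reads(self, sample: str, family: str) -> int:
        return self.total_reads(sample, family) - self.synthetic_reads(
            sample, family
        )

    def microbial_counts(self, family: str) -> pd.DataFrame:
        """Taxon rows only (synthetic category dropped) for one family."""
        sl = self.family_slice(family)
        return sl.loc[[c for c in sl.index if not c.startswith(SYNTHETIC_PREFIX)]]

    def drop_singletons(self) -> "CountTable":
        """Drop categories with a single read across all samples (optional
        dereplication path; synthetic categories are never dropped)."""
        totals = self.counts.sum(axis=1)
        keep = (totals != 1) | self.is_synthetic()
        return CountTable(self.counts.loc[keep], self.family.loc[keep])

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "family", self.family)
        out.to_csv(path, sep="\t", index_label="category")

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="category")
        family = df.pop("family")
        return cls(df.astype(int), family)


# ---------------------------------------------------------------------------
# Classification and the full pipeline


class _NearestReference:
    """Nearest-neighbour Hamming classifier over same-length references."""

    def __init__(
        self,
        spike_inserts: Dict[str, str],
        refs_by_family: Dict[str, List[Tuple[str, str]]],
        max_mismatches: int = 2,
    ) -> None:
        self.spike_inserts = spike_inserts
        self.refs = refs_by_family
        self.budget = max_mismatches

    def classify(self, family: str, insert: str) -> Optional[str]:
        best_label: Optional[str] = None
        best_d = self.budget + 1
        spike = self.spike_inserts.get(family)
        if spike is not None and len(spike) == len(insert):
            d = _hamming(spike, insert, self.budget)
            if d is not None and d < best_d:
                best_d, best_label = d, synthetic_category(family)
        for label, ref in self.refs.get(family, []):
            if len(ref) != len(insert):
                continue
            d = _hamming(ref, insert, self.budget)
            if d is None:
                continue
            if d < best_d or (d == best_d and (best_label is None or label < best_label)):
                best_d, best_label = d, label
        return best_label


def _hamming(a: str, b: str, budget: int) -> Optional[int]:
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > budget:
                return None
    return n


def classify_reads(
    reads_by_sample_family: Dict[Tuple[str, str], List[ReadRecord]],
    spikes: Dict[str, SpikeSpec],
    references: Sequence[Reference],
    primer_pairs: Dict[str, PrimerPair],
    max_mismatches: int = 2,
) -> Tuple[CountTable, pd.DataFrame]:
    """Count PBS-trimmed reads into synthetic/taxon categories per sample.

    Reads match the synthetic category when within the budget of their
    family's spike stuffer, otherwise the nearest reference label (ties to
    the lexicographically first), otherwise they are reported unassigned.
    Returns (CountTable, unassigned report with one row per sample/family).
    """
    families_present = {fam for (_, fam) in reads_by_sample_family}
    missing = [
        fam
        for fam in families_present
        if fam not in spikes and not any(r.family == fam for r in references)
    ]
    if missing:
        raise ValueError(f"no references for families with reads: {sorted(missing)}")

    refs_by_family: Dict[str, List[Tuple[str, str]]] = defaultdict(list)
    for ref in references:
        pair = primer_pairs[ref.family]
        insert = ref.amplicon[len(pair.forward) : len(ref.amplicon) - len(pair.reverse)]
        refs_by_family[ref.family].append((ref.label, insert))
    classifier = _NearestReference(
        {fam: s.stuffer for fam, s in spikes.items()}, dict(refs_by_family),
        max_mismatches,
    )

    cache: Dict[Tuple[str, str], Optional[str]] = {}
    counts: Dict[Tuple[str, str], Counter] = defaultdict(Counter)
    unassigned: Counter = Counter()
    samples: List[str] = []
    for (sample, fam), reads in reads_by_sample_family.items():
        if sample not in samples:
            samples.append(sample)
        for read in reads:
            key = (fam, read.sequence)
            if key in cache:
                label = cache[key]
            else:
                label = classifier.classify(fam, read.sequence)
                cache[key] = label
            if label is None:
                unassigned[(sample, fam)] += 1
            else:
                counts[(sample, fam)][label] += 1

    categories = [synthetic_category(f) for f in sorted(spikes)]
    family_tags = {synthetic_category(f): f for f in sorted(spikes)}
    for ref in references:
        if ref.label not in family_tags:
            categories.append(ref.label)
            family_tags[ref.label] = ref.family
    table = pd.DataFrame(0, index=categories, columns=sorted(samples), dtype=int)
    for (sample, fam), ctr in counts.items():
        for label, n in ctr.items():
            table.loc[label, sample] += n
    unassigned_df = pd.DataFrame(
        [
            {"sample": s, "family": f, "unassigned_reads": n}
            for (s, f), n in sorted(unassigned.items())
        ],
        columns=["sample", "family", "unassigned_reads"],
    )
    return CountTable(table, pd.Series(family_tags).loc[categories]), unassigned_df


@dataclass
class ProcessResult:
    """Full pipeline output with per-stage accounting.

    ``unassigned`` counts reads lost at each stage (demux, family,
    length, classify); input = table total + sum(unassigned) always.
    """

    count_table: CountTable
    retention: Dict[str, float]
    unassigned: pd.DataFrame
    n_input: int

    @property
    def n_counted(self) -> int:
        return int(self.count_table.counts.to_numpy().sum())

    @property
    def n_unassigned(self) -> int:
        return int(self.unassigned["reads"].sum())


def process_reads(
    reads: Iterable[ReadRecord],
    scheme: DemuxScheme,
    primer_pairs: Dict[str, PrimerPair],
    spikes: Dict[str, SpikeSpec],
    references: Sequence[Reference],
    *,
    windows: Dict[str, Tuple[int, int]] | None = None,
    barcode_mismatches: int = 0,
    primer_mismatches: int = 1,
    classify_mismatches: int = 2,
    drop_singletons: bool = False,
) -> ProcessResult:
    """Demultiplex, assign families, length-filter and classify in one pass.

    The per-read work is memoised on the raw sequence, so runs dominated by
    repeated sequences (e.g. error-free amplicons) cost one classification
    per unique read.
    """
    if windows is None:
        windows = {
            fam: pair.amplicon_length_window for fam, pair in primer_pairs.items()
        }
    pair_list = list(primer_pairs.values())
    refs_by_family: Dict[str, List[Tuple[str, str]]] = defaultdict(list)
    for ref in references:
        pair = primer_pairs[ref.family]
        insert = ref.amplicon[len(pair.forward) : len(ref.amplicon) - len(pair.reverse)]
        refs_by_family[ref.family].append((ref.label, insert))
    classifier = _NearestReference(
        {fam: s.stuffer for fam, s in spikes.items()}, dict(refs_by_family),
        classify_mismatches,
    )

    # sequence -> (sample, category, failure stage); sample is barcode-derived
    cache: Dict[str, Tuple[Optional[str], Optional[str], Optional[str]]] = {}
    counts: Dict[Tuple[str, str], int] = defaultdict(int)
    stage_losses: Counter = Counter()
    n_input = 0

    for read in reads:
        n_input += 1
        seq = read.sequence
        hit = cache.get(seq)
        if hit is None:
            hit = _process_one(
                seq, scheme, pair_list, windows, classifier,
                barcode_mismatches, primer_mismatches,
            )
            cache[seq] = hit
        sample, category, stage = hit
        if category is None:
            stage_losses[(sample, stage)] += 1
        else:
            counts[(sample, category)] += 1

    categories = [synthetic_category(f) for f in sorted(spikes)]
    family_tags = {synthetic_category(f): f for f in sorted(spikes)}
    for ref in references:
        if ref.label not in family_tags:
            categories.append(ref.label)
            family_tags[ref.label] = ref.family
    table = pd.DataFrame(0, index=categories, columns=scheme.samples, dtype=int)
    for (sample, category), n in counts.items():
        table.loc[category, sample] += n
    unassigned_df = pd.DataFrame(
        [
            {"sample": s if s is not None else "", "stage": stage, "reads": n}
            for (s, stage), n in sorted(
                stage_losses.items(), key=lambda kv: (str(kv[0][0]), str(kv[0][1]))
            )
        ],
        columns=["sample", "stage", "reads"],
    )

    count_table = CountTable(table, pd.Series(family_tags).loc[categories])
    if drop_singletons:
        count_table = count_table.drop_singletons()
    retention = _retention_from_losses(count_table, stage_losses)
    return ProcessResult(count_table, retention, unassigned_df, n_input)


def _retention_from_losses(
    count_table: CountTable, stage_losses: Counter
) -> Dict[str, float]:
    # reads reaching the length filter = counted + classify losses + length
    # losses; family-resolved stages carry "family:stage" markers
    kept = count_table.counts.groupby(count_table.family).sum().sum(axis=1)
    lost_len: Counter = Counter()
    lost_classify: Counter = Counter()
    for (sample, stage), n in stage_losses.items():
        if stage is None:
            continue
        if stage.startswith("length:"):
            lost_len[stage.split(":", 1)[1]] += n
        elif stage.startswith("classify:"):
            lost_classify[stage.split(":", 1)[1]] += n
    out: Dict[str, float] = {}
    for fam in count_table.families():
        n_kept = int(kept.get(fam, 0)) + lost_classify[fam]
        n_all = n_kept + lost_len[fam]
        out[fam] = n_kept / n_all if n_all else float("nan")
    return out


def _process_one(
    seq: str,
    scheme: DemuxScheme,
    primer_pairs: List[PrimerPair],
    windows: Dict[str, Tuple[int, int]],
    classifier: _NearestReference,
    barcode_mismatches: int,
    primer_mismatches: int,
) -> Tuple[Optional[str], Optional[str], Optional[str]]:
    sample, amplicon, _ = _demux_one(
        ReadRecord("r", seq), scheme, barcode_mismatches
    )
    if sample is None:
        return None, None, "demux"
    fam, insert = assign_family_seq(amplicon, primer_pairs, primer_mismatches)
    if fam is None:
        return sample, None, "family"
    lo, hi = windows[fam]
    if not lo <= len(amplicon) <= hi:
        return sample, None, f"length:{fam}"
    label = classifier.classify(fam, insert)
    if label is None:
        return sample, None, f"classify:{fam}"
    return sample, label, None
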