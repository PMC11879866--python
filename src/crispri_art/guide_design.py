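"""crRNA spacer design and oligo-pool encoding.

Two designers are provided.  The RBS panel places a small number of
spacers (default 7, stepped 5 nt apart) antisense to the translation
initiation region of each CDS, so that their 31-nt target windows
collectively span the ribosome-binding site and start codon.  The
single-nucleotide tiler emits one spacer per position of a transcript
region (optionally extended 100 nt beyond its ends).

Designed spacers are wrapped into 100-nt amplifiable synthesis oligos
with subpool-specific primers and BsaI Golden Gate sites; oligos whose
sequence acquires an internal BsaI site are excluded, duplicate spacers
are deduplicated, and candidate libraries can be scanned for off-target
matches (Hamming distance <= 2) against susceptible RBS windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._util import gc_fraction, hamming, revcomp
from .genome_io import GeneFeature, GenomeRecord, TranscriptRegion, extract_window

logger = logging.getLogger(__name__)

BSAI_SITE = "GGTCTC"
BSAI_SITE_RC = "GAGACC"

#: 4-nt Golden Gate overhangs of the crRNA entry vector.
UPSTREAM_OVERHANG = "AAAC"
DOWNSTREAM_OVERHANG = "TGCT"

SPACER_LEN = 31


@dataclass(frozen=True)
class GuideRecord:
    """One crRNA spacer and the mRNA window it base-pairs with.

    ``spacer`` is the synthesized crRNA spacer (antisense to the mRNA for
    targeting guides); ``target_window`` is the mRNA-sense protospacer;
    ``target_start`` is the offset of the window's first (5'-most mRNA)
    base relative to the start codon's first base (0 = A of ATG,
    negative = upstream).
    """

    guide_id: str
    gene_id: str
    spacer: str
    target_start: int
    target_window: str
    library_tag: str = "rbs_panel"  # rbs_panel | nt_tiling | control_sense | nontargeting


@dataclass(frozen=True)
class SubpoolPrimerPair:
    """Orthogonal 20-nt primer pair amplifying one subpool (top-strand sequences)."""

    subpool_id: str
    fwd: str
    rev: str

    def __post_init__(self) -> None:
        for name, p in (("fwd", self.fwd), ("rev", self.rev)):
            if len(p) != 20:
                raise ValueError(f"{name} primer must be 20 nt, got {len(p)}")
            if BSAI_SITE in p or BSAI_SITE_RC in p:
                raise ValueError(f"{name} primer contains a BsaI site: {p}")


@dataclass(frozen=True)
class OligoRecord:
    """A 100-nt synthesis oligo wrapping one spacer.

    ``element_map`` lists the seven elements in order as
    ``(name, start, end)`` half-open coordinates within ``full_sequence``.
    """

    guide_id: str
    subpool_id: str
    full_sequence: str
    element_map: tuple[tuple[str, int, int], ...]

    def element(self, name: str) -> str:
        for n, s, e in self.element_map:
            if n == name:
                return self.full_sequence[s:e]
        raise KeyError(name)

    @property
    def n_bsai_sites(self) -> int:
        return count_bsai_sites(self.full_sequence)


@dataclass(frozen=True)
class OffTargetHit:
    guide_id: str
    target_record_id: str
    gene_id: str
    mismatches: int
    position: int


@dataclass(frozen=True)
class DigestFragment:
    """Central dsDNA fragment released by simulated BsaI digestion."""

    top_strand: str          # full 40-nt extent including both overhang tracts
    overhang5: str           # 5' overhang at the upstream cut (top strand)
    overhang3: str           # 5' overhang at the downstream cut (bottom strand)

    @property
    def length(self) -> int:
        return len(self.top_strand)


def count_bsai_sites(seq: str) -> int:
    """Number of BsaI recognition sites on either strand (overlap-aware)."""
    n = 0
    for site in (BSAI_SITE, BSAI_SITE_RC):
        start = 0
        while True:
            i = seq.find(site, start)
            if i == -1:
                break
            n += 1
            start = i + 1
    return n


# ---------------------------------------------------------------------------
# Spacer design
# ---------------------------------------------------------------------------

def _window_starts(n_guides: int, step: int, spacer_len: int,
                   window_center_offset: int) -> list[int]:
    # Window centers at window_center_offset + step*(i - (n-1)/2); the start
    # is derived from the 5' end so odd and even spacer lengths behave the
    # same ((len-1)//2 bases left of the center).
    half = (spacer_len - 1) // 2
    first_center = window_center_offset - step * ((n_guides - 1) // 2)
    # for even n_guides the grid is shifted half a step toward the upstream side
    if n_guides % 2 == 0:
        first_center = window_center_offset - step * (n_guides // 2) + step // 2
    return [first_center + step * i - half for i in range(n_guides)]


def design_rbs_panel(
    genome: GenomeRecord,
    features: list[GeneFeature],
    n_guides: int = 7,
    step: int = 5,
    spacer_len: int = SPACER_LEN,
    window_center_offset: int = 0,
) -> list[GuideRecord]:
    """Per-gene panel of spacers tiled across the RBS/start-codon region.

    Defaults place 7 windows whose centers sit at -15, -10, ... +15 nt
    relative to the start codon (target windows collectively spanning
    -30 .. +30), guaranteeing at least one window that overlaps both the
    RBS and the start codon.  Guides whose window would run past a linear
    sequence end are dropped with a warning rather than shifted.
    """
    if not features:
        raise ValueError("design_rbs_panel requires a non-empty feature list")
    if n_guides < 1 or step < 1:
        raise ValueError("n_guides and step must be >= 1")
    starts = _window_starts(n_guides, step, spacer_len, window_center_offset)
    upstream_need = max(0, -min(starts))
    guides: list[GuideRecord] = []
    for feat in features:
        downstream_need = max(0, max(starts) + spacer_len - feat.length)
        try:
            region = extract_window(genome, feat, upstream_need, downstream_need)
        except ValueError as exc:
            logger.warning("skipping gene %s: %s", feat.gene_id, exc)
            continue
        for k, ts in enumerate(starts, start=1):
            i = region.anchor_offset + ts
            if i < 0 or i + spacer_len > len(region):
                logger.warning(
                    "dropping guide %d of %s: window [%+d, %+d) exceeds the "
                    "linear sequence", k, feat.gene_id, ts, ts + spacer_len,
                )
                continue
            window = region.mrna_sequence[i:i + spacer_len]
            guides.append(GuideRecord(
                guide_id=f"{feat.gene_id}_crRNA{k}",
                gene_id=feat.gene_id,
                spacer=revcomp(window),
                target_start=ts,
                target_window=window,
                library_tag="rbs_panel",
            ))
    return guides


def design_nt_tiling(
    region: TranscriptRegion,
    spacer_len: int = SPACER_LEN,
    sense: str = "antisense",
) -> list[GuideRecord]:
    """One spacer per position of ``region`` (single-nucleotide tiling).

    The region should already include any desired extension beyond the
    transcript ends (see :func:`design_nt_tiling_for_gene`); the guide
    count is ``len(region) - spacer_len + 1``.  ``sense="sense"`` emits
    non-targeting control spacers identical to the mRNA windows.
    """
    if sense not in ("antisense", "sense"):
        raise ValueError("sense must be 'antisense' or 'sense'")
    if len(region) < spacer_len:
        logger.warning(
            "region %s (%d nt) shorter than spacer length %d; no guides",
            region.gene_id, len(region), spacer_len,
        )
        return []
    tag = "nt_tiling" if sense == "antisense" else "control_sense"
    guides = []
    for i in range(len(region) - spacer_len + 1):
        window = region.mrna_sequence[i:i + spacer_len]
        ts = i - region.anchor_offset
        guides.append(GuideRecord(
            guide_id=f"{region.gene_id}_{tag}_{ts:+d}",
            gene_id=region.gene_id,
            spacer=revcomp(window) if sense == "antisense" else window,
            target_start=ts,
            target_window=window,
            library_tag=tag,
        ))
    return guides


def design_nt_tiling_for_gene(
    genome: GenomeRecord,
    feature: GeneFeature,
    extension: int = 100,
    spacer_len: int = SPACER_LEN,
    sense: str = "antisense",
) -> list[GuideRecord]:
    """Single-nucleotide tiling of a CDS extended ``extension`` nt both ways."""
    region = extract_window(genome, feature, extension, extension)
    return design_nt_tiling(region, spacer_len=spacer_len, sense=sense)


# ---------------------------------------------------------------------------
# Oligo encoding
# ---------------------------------------------------------------------------

_ELEMENT_ORDER = ("fwd_primer", "bsai_up", "spacer", "junction",
                  "bsai_down", "rev_primer", "pad")


def assemble_oligos(
    guides: list[GuideRecord],
    primer_pair: SubpoolPrimerPair,
    junction_base: str = "A",
    seed: int = 0,
    pad_len: int = 6,
) -> list[OligoRecord]:
    """Wrap spacers into 100-nt synthesis oligos.

    Layout (5'->3'): 20-nt subpool forward primer | 11-nt upstream BsaI
    site + AAAC overhang | 31-nt spacer | 1-nt junction preserving the
    first base of the entry-vector terminator | 11-nt TGCT overhang +
    downstream BsaI site | 20-nt subpool reverse primer (top strand) |
    6-nt arbitrary pad.  The pad and the single arbitrary base inside
    each BsaI element are drawn deterministically from ``seed`` and
    re-drawn (bounded) if they would create a spurious BsaI site.
    """
    if len(junction_base) != 1 or junction_base not in "ACGT":
        raise ValueError("junction_base must be a single A/C/G/T base")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    oligos = []
    for g in guides:
        if len(g.spacer) != SPACER_LEN:
            raise ValueError(
                f"guide {g.guide_id}: oligo layout requires a {SPACER_LEN}-nt "
                f"spacer, got {len(g.spacer)}"
            )
        for _attempt in range(20):
            n_up, n_down = rng.choice(bases, size=2)
            pad = "".join(rng.choice(bases, size=pad_len))
            bsai_up = BSAI_SITE + n_up + UPSTREAM_OVERHANG
            bsai_down = DOWNSTREAM_OVERHANG + n_down + BSAI_SITE_RC
            elements = {
                "fwd_primer": primer_pair.fwd,
                "bsai_up": bsai_up,
                "spacer": g.spacer,
                "junction": junction_base,
                "bsai_down": bsai_down,
                "rev_primer": primer_pair.rev,
                "pad": pad,
            }
            full = "".join(elements[n] for n in _ELEMENT_ORDER)
            if count_bsai_sites(full) == 2:
                break
            # a clean retry only helps if the spurious site involves the
            # arbitrary bases; spacer-borne sites persist and are flagged
            # downstream by filter_bsai
            spacer_clean = count_bsai_sites(g.spacer) == 0
            if not spacer_clean:
                break
        element_map = []
        pos = 0
        for n in _ELEMENT_ORDER:
            element_map.append((n, pos, pos + len(elements[n])))
            pos += len(elements[n])
        oligos.append(OligoRecord(g.guide_id, primer_pair.subpool_id, full,
                                  tuple(element_map)))
    return oligos


def filter_bsai(oligos: list[OligoRecord]) -> tuple[list[OligoRecord], list[tuple[OligoRecord, str]]]:
    """Exclude oligos with internal BsaI sites.

    Kept oligos contain exactly the two designed recognition sites (one
    per orientation); anything else is excluded with a reason string.
    """
    kept, excluded = [], []
    for o in oligos:
        n = o.n_bsai_sites
        if n == 2:
            kept.append(o)
        else:
            excluded.append((o, f"{n} BsaI recognition sites (expected 2)"))
    return kept, excluded


def simulate_bsai_digest(oligo: OligoRecord) -> DigestFragment:
    """Cut the oligo with BsaI in silico and return the central insert.

    BsaI (GGTCTC(N1)) cleaves outside its recognition site leaving 4-nt
    5' overhangs.  A valid oligo yields a 40-nt insert (4-nt AAAC overhang
    + 31-nt spacer + 1-nt junction + 4-nt TGCT tract) whose overhangs are
    AAAC (top, upstream) and AGCA (bottom strand of TGCT, downstream).
    """
    seq = oligo.full_sequence
    if count_bsai_sites(seq) != 2:
        raise ValueError(
            f"oligo {oligo.guide_id} has {count_bsai_sites(seq)} BsaI sites; "
            "digestion is only defined for the designed two-site layout"
        )
    p = seq.find(BSAI_SITE)
    q = seq.find(BSAI_SITE_RC)
    if p == -1 or q == -1 or q <= p:
        raise ValueError(f"oligo {oligo.guide_id}: BsaI sites not in the designed orientation")
    # top-strand site at p: top cut after p+6 (one spacer base), bottom after p+10
    # bottom-strand site (GAGACC at q on top): top cut before q-5, bottom before q-1
    top_cut_left = p + 7
    bottom_cut_right = q - 1
    return DigestFragment(
        top_strand=seq[top_cut_left:bottom_cut_right],
        overhang5=seq[top_cut_left:top_cut_left + 4],
        overhang3=revcomp(seq[bottom_cut_right - 4:bottom_cut_right]),
    )


def deduplicate_guides(
    guides: list[GuideRecord],
) -> tuple[list[GuideRecord], list[tuple[GuideRecord, str]]]:
    """Keep the first occurrence of each spacer sequence (design order).

    Returns ``(unique, dropped)`` where each dropped record is paired with
    the guide_id of the retained copy of its spacer.
    """
    seen: dict[str, str] = {}
    unique, dropped = [], []
    for g in guides:
        keeper = seen.get(g.spacer)
        if keeper is None:
            seen[g.spacer] = g.guide_id
            unique.append(g)
        else:
            dropped.append((g, keeper))
    return unique, dropped


# ---------------------------------------------------------------------------
# Off-target scanning
# ---------------------------------------------------------------------------

def build_rbs_regions(
    genome: GenomeRecord,
    features: list[GeneFeature],
    flank: int = 35,
) -> list[TranscriptRegion]:
    """Susceptible RBS windows: start codon +/- ``flank`` nt of every gene."""
    regions = []
    for f in features:
        region = extract_window(genome, f, flank, 0)
        end = min(len(region), region.anchor_offset + flank + 1)
        regions.append(TranscriptRegion(
            f.gene_id, region.mrna_sequence[:end], region.anchor_offset,
        ))
    return regions


def scan_offtargets(
    guides: list[GuideRecord],
    rbs_regions: list[TranscriptRegion],
    max_mismatch: int = 2,
    record_id: str = "",
) -> list[OffTargetHit]:
    """Hamming-only scan of each guide's protospacer against RBS windows.

    A hit is any (guide, region) pair where the reverse complement of the
    spacer matches a region substring with <= ``max_mismatch`` mismatches;
    matches to the guide's own gene are suppressed.  Indels and G-U wobble
    pairing are not modelled.
    """
    hits = []
    for g in guides:
        target = revcomp(g.spacer)
        L = len(target)
        for region in rbs_regions:
            if region.gene_id == g.gene_id:
                continue
            seq = region.mrna_sequence
            for i in range(len(seq) - L + 1):
                d = hamming(target, seq[i:i + L], limit=max_mismatch)
                if d <= max_mismatch:
                    hits.append(OffTargetHit(g.guide_id, record_id,
                                             region.gene_id, d, i))
    return hits


# ---------------------------------------------------------------------------
# Subpool primers
# ---------------------------------------------------------------------------

def generate_orthogonal_primers(
    n_pairs: int,
    length: int = 20,
    min_pairwise_hamming: int = 8,
    gc_range: tuple[float, float] = (0.4, 0.6),
    seed: int = 0,
    max_attempts: int = 20_000,
) -> list[SubpoolPrimerPair]:
    """Random-search construction of mutually orthogonal subpool primers.

    All ``2 * n_pairs`` primers (and their reverse complements) are
    pairwise at Hamming distance >= ``min_pairwise_hamming``, BsaI-free
    and within ``gc_range``.  Deterministic under ``seed``; raises if the
    constraints cannot be met within ``max_attempts`` candidate draws.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    accepted: list[str] = []

    def compatible(cand: str) -> bool:
        rc = revcomp(cand)
        if hamming(cand, rc) < min_pairwise_hamming:
            return False
        for p in accepted:
            if (hamming(cand, p) < min_pairwise_hamming
                    or hamming(cand, revcomp(p)) < min_pairwise_hamming):
                return False
        return True

    attempts = 0
    while len(accepted) < 2 * n_pairs:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not find {2 * n_pairs} orthogonal primers within "
                f"{max_attempts} attempts; relax gc_range or "
                "min_pairwise_hamming, or reduce n_pairs"
            )
        attempts += 1
        cand = "".join(rng.choice(bases, size=length))
        if not (gc_range[0] <= gc_fraction(cand) <= gc_range[1]):
            continue
        if BSAI_SITE in cand or BSAI_SITE_RC in cand:
            continue
        if compatible(cand):
            accepted.append(cand)
    return [
        SubpoolPrimerPair(f"subpool_{i + 1}", accepted[2 * i], accepted[2 * i + 1])
        for i in range(n_pairs)
    ]


# ---------------------------------------------------------------------------
# Tabular export
# ---------------------------------------------------------------------------

def guides_to_table(guides: list[GuideRecord]):
    import pandas as pd

    return pd.DataFrame(
        [(g.guide_id, g.gene_id, g.spacer, g.target_start, g.library_tag)
         for g in guides],
        columns=["guide_id", "gene_id", "spacer", "target_start", "library_tag"],
    )


def oligos_to_table(oligos: list[OligoRecord]):
    import pandas as pd

    rows = []
    for o in oligos:
        emap = ";".join(f"{n}:{s}-{e}" for n, s, e in o.element_map)
        rows.append((o.guide_id, o.subpool_id, o.full_sequence, emap))
    return pd.DataFrame(rows, columns=["guide_id", "subpool_id",
                                       "full_sequence", "element_map"])
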