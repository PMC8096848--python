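"""miRNA seed-site scanning, evidence integration and ARE half-site scanning.

Implements the canonical TargetScan-style site taxonomy. For a mature miRNA
read 5'->3', the seed is nucleotides 2-8. Site patterns on the target mRNA
(written as DNA, 5'->3') are:

* 7mer-m8 : reverse complement of miRNA positions 2-8
* 8mer    : 7mer-m8 followed by an A opposite miRNA position 1
* 6mer    : reverse complement of miRNA positions 2-7
* 7mer-A1 : 6mer followed by an A opposite position 1

The A1 adenine is a property of the target site, not complementarity, so it
is a literal "A" regardless of the miRNA's first nucleotide.

The androgen-receptor half-site scan looks for the ARE hexamer AGAACA in
promoter sequences on both strands, reporting TSS-relative upstream
coordinates (-1 = the base immediately 5' of the TSS).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from Bio.Seq import Seq

# Mature hsa-miR-125b-5p (miRBase MIMAT0000423). External knowledge shipped
# as a convenience default; callers can supply any mature sequence.
MIR125B_5P = "UCCCUGAGACCCUAACUUGUGA"

ARE_HALF_SITE = "AGAACA"

# most specific first; used for overlap resolution and reporting order
SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1", "6mer")


def _revcomp_rna_to_dna(rna: str) -> str:
    """Reverse complement an RNA string, written as DNA."""
    return str(Seq(rna.replace("U", "T")).reverse_complement())


@dataclass(frozen=True)
class MirnaSeed:
    """A mature miRNA with its compiled DNA site patterns."""

    mature: str
    seed: str
    patterns: dict[str, str] = field(hash=False)

    @property
    def longest_pattern(self) -> int:
        return max(len(p) for p in self.patterns.values())


def compile_seed_patterns(mirna_seq: str) -> MirnaSeed:
    """Compile the four canonical seed-match patterns from a mature miRNA.

    Parameters
    ----------
    mirna_seq : mature miRNA sequence, RNA alphabet (ACGU), 5'->3',
        length >= 8.
    """
    seq = mirna_seq.strip().upper().replace("T", "U")
    if len(seq) < 8:
        raise ValueError(f"mature miRNA must be >= 8 nt, got {len(seq)}")
    if set(seq) - set("ACGU"):
        raise ValueError(f"invalid characters in miRNA sequence: {sorted(set(seq) - set('ACGU'))}")
    seed = seq[1:8]                       # positions 2-8, 1-based
    m8 = _revcomp_rna_to_dna(seq[1:8])    # 7mer-m8
    six = _revcomp_rna_to_dna(seq[1:7])   # 6mer (positions 2-7)
    patterns = {
        "8mer": m8 + "A",
        "7mer-m8": m8,
        "7mer-A1": six + "A",
        "6mer": six,
    }
    return MirnaSeed(mature=seq, seed=seed, patterns=patterns)


@dataclass(frozen=True)
class SeedSite:
    """One seed-match occurrence; start/end are 1-based inclusive."""

    gene_id: str
    site_type: str
    start: int
    end: int
    matched: str


def _validate_dna(seq: str, what: str = "sequence") -> str:
    s = seq.strip().upper()
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"invalid characters in {what}: {sorted(bad)}")
    return s


def scan_utr(utr_seq: str, seed: MirnaSeed, gene_id: str = "") -> list[SeedSite]:
    """Find all seed-match sites in a 3'-UTR.

    Where site types overlap at the same locus only the most specific is
    reported (8mer > 7mer-m8 > 7mer-A1 > 6mer). Overlapping occurrences of
    equally or less specific types at other offsets are suppressed too, so
    each UTR position belongs to at most one reported site.
    """
    s = _validate_dna(utr_seq, "UTR")
    covered = np.zeros(len(s), dtype=bool)
    sites: list[SeedSite] = []
    for site_type in SITE_TYPES:
        pat = seed.patterns[site_type]
        start = s.find(pat)
        while start != -1:
            end = start + len(pat)  # exclusive
            if not covered[start:end].any():
                covered[start:end] = True
                sites.append(
                    SeedSite(gene_id=gene_id, site_type=site_type,
                             start=start + 1, end=end, matched=pat)
                )
            start = s.find(pat, start + 1)
    sites.sort(key=lambda x: x.start)
    return sites


def inverse_targets(mir_expr: np.ndarray, gene_matrix, r_threshold: float = 0.3) -> set[str]:
    """Genes whose expression is inversely correlated with the miRNA.

    Returns the set with Pearson r < -r_threshold against ``mir_expr``.
    """
    from .de import pearson_r

    if not 0 < r_threshold < 1:
        raise ValueError("r_threshold must be in (0, 1)")
    mir = np.asarray(mir_expr, dtype=float)
    if len(mir) != gene_matrix.n_samples:
        raise ValueError(
            f"miRNA vector length {len(mir)} does not match "
            f"{gene_matrix.n_samples} samples"
        )
    hits = set()
    for i, g in enumerate(gene_matrix.gene_ids):
        row = gene_matrix.values[i]
        if np.std(row) == 0:
            continue
        r, _ = pearson_r(mir, row)
        if r < -r_threshold:
            hits.add(g)
    return hits


@dataclass
class EvidenceSets:
    """Three evidence sets and their Venn decomposition.

    final is the triple intersection — the predicted high-confidence
    target list (site match AND down after mimic transfection AND
    inversely correlated in patients).
    """

    predicted: set[str]
    transfection_down: set[str]
    patient_inverse: set[str]
    final: set[str]
    region_counts: dict[tuple[bool, bool, bool], int]


def integrate_evidence(
    predicted: set[str], transfection_down: set[str], patient_inverse: set[str]
) -> EvidenceSets:
    """Three-way intersection of target evidence with full Venn counts."""
    predicted = set(predicted)
    transfection_down = set(transfection_down)
    patient_inverse = set(patient_inverse)
    union = predicted | transfection_down | patient_inverse
    counts: dict[tuple[bool, bool, bool], int] = {}
    for g in union:
        key = (g in predicted, g in transfection_down, g in patient_inverse)
        counts[key] = counts.get(key, 0) + 1
    return EvidenceSets(
        predicted=predicted,
        transfection_down=transfection_down,
        patient_inverse=patient_inverse,
        final=predicted & transfection_down & patient_inverse,
        region_counts=counts,
    )


@dataclass(frozen=True)
class HalfSite:
    """An ARE half-site occurrence in a promoter.

    Coordinates are upstream positions relative to the TSS: -1 is the base
    immediately 5' of the TSS. near/far are the motif ends, |near| < |far|;
    the site is reported as "-near/-far" in text output.
    """

    near: int
    far: int
    strand: str
    matched: str

    def label(self) -> str:
        return f"-{self.near}/-{self.far}"


def scan_promoter_halfsites(
    promoter_seq: str, motif: str = ARE_HALF_SITE, span: int = 2000
) -> list[HalfSite]:
    """Scan a promoter for ARE half-sites on both strands.

    ``promoter_seq`` is the region immediately upstream of the TSS, ending
    at the base 5'-adjacent to it. Sequences longer than ``span`` are
    truncated (with a warning) to the ``span`` bases nearest the TSS.
    Reverse-strand hits are forward occurrences of the motif's reverse
    complement. Results are ordered left to right along the sequence.
    """
    s = _validate_dna(promoter_seq, "promoter")
    motif = _validate_dna(motif, "motif")
    if len(s) > span:
        warnings.warn(
            f"promoter length {len(s)} exceeds span {span}; "
            f"keeping the {span} bases nearest the TSS"
        )
        s = s[-span:]
    L = len(s)
    rc = str(Seq(motif).reverse_complement())
    hits: list[HalfSite] = []
    for pat, strand in ((motif, "+"), (rc, "-")):
        start = s.find(pat)
        while start != -1:
            stop = start + len(pat) - 1  # inclusive index
            # index i maps to upstream position i - L (negative)
            hits.append(
                HalfSite(near=L - stop, far=L - start, strand=strand, matched=pat)
            )
            start = s.find(pat, start + 1)
    hits.sort(key=lambda h: (-h.far, h.strand))
    return hits
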