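"""Annotated antibody variable-domain references.

An antibody V domain is a contiguous stretch of six regions
(FR1, CDR1, FR2, CDR2, FR3, CDR3) read in a single frame, with invariant
cysteine and tryptophan residues anchoring the framework.  References here
play the role of Sanger-verified control sequences: every simulated read and
every error call is made relative to one of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

REGION_ORDER = ("FR1", "CDR1", "FR2", "CDR2", "FR3", "CDR3")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
DEFAULT_LAYOUT = {
    "FR1": 78,
    "CDR1": 24,
    "FR2": 51,
    "CDR2": 30,
    "FR3": 114,
    "CDR3": 33,
}

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_codon(codon: str) -> str:
    """Translate one codon; any codon with a non-ACGT character maps to 'X'."""
    return _CODON_TABLE.get(codon.upper(), "X")


@dataclass
class ReferenceSequence:
    """A Sanger-verified V-domain nucleotide sequence with region annotation.

    Parameters
    ----------
    id : str
        Sequence identifier (FASTA header).
    seq : str
        Nucleotide sequence over ``{A,C,G,T}``.
    frame_offset : int
        0-based nucleotide offset of the reading frame (0-2).
    regions : dict[str, tuple[int, int]]
        Ordered mapping of region label to half-open nucleotide interval.
        Intervals must tile a contiguous span without overlap.
    conserved_positions : list[tuple[int, str]]
        ``(codon index, expected amino acid)`` pairs, amino acid in
        ``{C, W}`` (the invariant framework cysteines / tryptophan).
    """

    id: str
    seq: str
    frame_offset: int = 0
    regions: dict[str, tuple[int, int]] = field(default_factory=dict)
    conserved_positions: list[tuple[int, str]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.seq)

    def region_of(self, pos: int) -> str | None:
        """Region label whose half-open interval contains ``pos``, else None."""
        for label, (start, end) in self.regions.items():
            if start <= pos < end:
                return label
        return None

    def translate(self) -> str:
        """Amino-acid translation from ``frame_offset``; trailing bases dropped."""
        s = self.seq[self.frame_offset:]
        return "".join(
            translate_codon(s[i:i + 3]) for i in range(0, len(s) - 2, 3)
        )

    def validate(self) -> None:
        """Raise ``ValueError`` on any violated invariant."""
        if not self.seq:
            raise ValueError("empty reference sequence")
        bad = set(self.seq) - set("ACGT")
        if bad:
            raise ValueError(f"non-ACGT characters in reference: {sorted(bad)}")
        if not 0 <= self.frame_offset <= 2:
            raise ValueError(f"frame_offset must be 0-2, got {self.frame_offset}")
        if self.regions:
            labels = list(self.regions)
            if any(lab not in REGION_ORDER for lab in labels):
                raise ValueError(f"unknown region label in {labels}")
            ivals = list(self.regions.values())
            for (s, e) in ivals:
                if not 0 <= s < e <= self.length:
                    raise ValueError(f"region interval ({s}, {e}) out of bounds")
            for (_, e_prev), (s_next, _) in zip(ivals, ivals[1:]):
                if e_prev != s_next:
                    raise ValueError("regions must tile a contiguous span")
        prot = self.translate()
        if "*" in prot:
            raise ValueError(f"internal stop codon at codon {prot.index('*')}")
        for codon_idx, aa in self.conserved_positions:
            start = self.frame_offset + 3 * codon_idx
            got = translate_codon(self.seq[start:start + 3])
            if got != aa:
                raise ValueError(
                    f"conserved codon {codon_idx} translates to {got}, expected {aa}"
                )


def homopolymer_runs(seq: str) -> list[tuple[int, int, str]]:
    """Maximal single-base runs of ``seq`` as ``(start, end, base)`` triples."""
    runs = []
    i, n = 0, len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        runs.append((i, j, seq[i]))
        i = j
    return runs


def run_length_at(seq: str, pos: int) -> tuple[str, int]:
    """Base and length of the maximal run containing position ``pos``."""
    if not 0 <= pos < len(seq):
        raise ValueError(f"position {pos} outside sequence of length {len(seq)}")
    b = seq[pos]
    s = pos
    while s > 0 and seq[s - 1] == b:
        s -= 1
    e = pos + 1
    while e < len(seq) and seq[e] == b:
        e += 1
    return b, e - s


def _sample_codon(rng: np.random.Generator, gc_bias: float) -> str:
    p_gc = gc_bias / 2.0
    p_at = (1.0 - gc_bias) / 2.0
    probs = [p_at, p_gc, p_gc, p_at]  # A, C, G, T
    while True:
        codon = "".join(rng.choice(list("ACGT"), size=3, p=probs))
        if codon not in STOP_CODONS:
            return codon


def generate_reference(
    layout: dict[str, int] | None = None,
    gc_bias: float = 0.5,
    polyg_hotspots: int = 2,
    seed: int = 0,
    ref_id: str = "ref",
) -> ReferenceSequence:
    """Generate a random antibody-like reference satisfying all invariants.

    The sequence is built codon-by-codon (stop codons rejected), conserved
    Cys/Trp codons are written at the canonical framework anchors (end of
    FR1, start of FR2, end of FR3), and ``polyg_hotspots`` G-runs of length
    2-4 are planted, at least one inside CDR1 — mimicking the polyG hotspots
    at CDR1 codons 27/29 where pyrosequencing miscounts run lengths.

    Deterministic for a fixed ``seed``.
    """
    layout = dict(layout or DEFAULT_LAYOUT)
    if set(layout) - set(REGION_ORDER):
        raise ValueError(f"unknown region labels: {set(layout) - set(REGION_ORDER)}")
    if any(v <= 0 for v in layout.values()):
        raise ValueError("region lengths must be positive")
    total = sum(layout.values())
    if total < 150:
        raise ValueError(f"total length {total} < 150 nt")
    if total % 3:
        raise ValueError("total length must be a multiple of 3 to keep frame")

    regions: dict[str, tuple[int, int]] = {}
    pos = 0
    for label in REGION_ORDER:
        if label in layout:
            regions[label] = (pos, pos + layout[label])
            pos += layout[label]

    rng = np.random.default_rng(seed)
    for _attempt in range(200):
        codons = [_sample_codon(rng, gc_bias) for _ in range(total // 3)]
        seq = list("".join(codons))

        conserved: list[tuple[int, str]] = []
        if "FR1" in regions:
            ci = regions["FR1"][1] // 3 - 1
            seq[3 * ci:3 * ci + 3] = "TGC"
            conserved.append((ci, "C"))
        if "FR2" in regions:
            ci = regions["FR2"][0] // 3
            if regions["FR2"][0] % 3 == 0:
                seq[3 * ci:3 * ci + 3] = "TGG"
                conserved.append((ci, "W"))
        if "FR3" in regions:
            ci = regions["FR3"][1] // 3 - 1
            seq[3 * ci:3 * ci + 3] = "TGC"
            conserved.append((ci, "C"))

        # plant polyG hotspots: first inside CDR1, the rest anywhere interior
        hotspot_spans = []
        if polyg_hotspots > 0:
            targets = []
            if "CDR1" in regions:
                targets.append(regions["CDR1"])
            while len(targets) < polyg_hotspots:
                targets.append((3, total - 3))
            for (lo, hi) in targets[:polyg_hotspots]:
                run_len = int(rng.integers(2, 5))
                lo = max(lo, 3)
                hi = min(hi, total - 3) - run_len
                if hi <= lo:
                    continue
                start = int(rng.integers(lo, hi))
                seq[start:start + run_len] = "G" * run_len
                hotspot_spans.append((start, start + run_len))

        ref = ReferenceSequence(
            id=ref_id,
            seq="".join(seq),
            frame_offset=0,
            regions=regions,
            conserved_positions=conserved,
        )
        try:
            ref.validate()
        except ValueError:
            continue
        g_runs = [r for r in homopolymer_runs(ref.seq) if r[2] == "G" and 2 <= r[1] - r[0] <= 4]
        if len(g_runs) < polyg_hotspots:
            continue
        if polyg_hotspots > 0 and "CDR1" in regions:
            c0, c1 = regions["CDR1"]
            if not any(s < c1 and e > c0 for s, e, _ in g_runs):
                continue
        return ref
    raise RuntimeError("failed to generate a valid reference; relax the layout")
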