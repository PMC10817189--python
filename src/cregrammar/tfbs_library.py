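"""Design and encoding of synthetic cis-regulatory element (CRE) libraries.

Synthetic CREs are ordered arrangements of transcription-factor binding
sites (TFBSs), each site drawn from a small alphabet of single-character
codes that record the TF family (CRX, NRL, NEUROD1, RORB, MAZ), the site
affinity (high / medium / low), and the orientation (forward / reverse).
Two built-in libraries are provided:

``crx_nrl``
    Up to four CRX/NRL sites in either orientation, cloned next to the
    murine *Rho* or *Hsp68* basal promoter.  Its 8 site tokens are the
    three CRX affinity classes in two orientations plus the NRL consensus
    in two orientations.

``cdnrm``
    Five forward-orientation sites for CRX, NEUROD1, NRL, RORB and MAZ
    next to the *Rho* promoter, composed as 3-1-1 or 2-2-1 mixtures of
    TF identities.

Arrangements are exported either as fixed-length symbolic strings (pad
character ``O`` prepended, promoter character appended) for model fitting,
or as nucleotide sequences built from 20-bp building blocks
(``AGCTAC<12-bp motif>GT``) that maintain helical spacing between sites.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "SiteToken",
    "Alphabet",
    "CREDesign",
    "MOTIFS",
    "make_alphabet",
    "build_block",
    "design_to_nucleotide",
    "enumerate_exhaustive",
    "sample_arrangements",
    "enumerate_composition_arrangements",
    "design_cdnrm_library",
    "encode_fixed",
    "encode_binned",
    "designs_to_table",
    "designs_to_fasta",
]

# 12-bp motif sequences for each (TF family, affinity).  The NRL consensus
# used in the CRX-NRL library is a distinct sequence that is not part of
# this set; crx_nrl NRL tokens therefore carry an empty motif and nucleotide
# export for them requires an explicit override.
MOTIFS: dict[tuple[str, str], str] = {
    ("CRX", "high"): "TGCTAATCCCAC",
    ("CRX", "medium"): "TGCTAAGCCAAC",
    ("CRX", "low"): "TGCTGATTCAAC",
    ("NRL", "high"): "AATTTGCTGACC",
    ("NRL", "medium"): "GGCCTGCTGACC",
    ("NEUROD1", "high"): "CAACAGATGGTA",
    ("NEUROD1", "medium"): "CGGCAGGTGGTA",
    ("RORB", "high"): "AATTAGGTCACT",
    ("RORB", "medium"): "ATCTGGGTCAGT",
    ("MAZ", "high"): "GGGGGAGGGGGG",
    ("MAZ", "medium"): "GCGGGCGGGGGG",
}

BLOCK_PREFIX = "AGCTAC"
BLOCK_SUFFIX = "GT"
PAD_CODE = "O"
PAD_ALIASES = ("_",)  # figure captions use "_" for the placeholder site


class LibraryConfigError(ValueError):
    """Inconsistent alphabet or library specification."""


@dataclass(frozen=True)
class SiteToken:
    """One binding-site identity: code, TF family, affinity, orientation.

    Special tokens (pad, promoter, background) use ``tf="special"`` and
    ``affinity=orientation="n/a"``.
    """

    code: str
    tf: str
    affinity: str = "n/a"
    orientation: str = "n/a"
    motif: str = ""

    def __post_init__(self):
        if len(self.code) != 1:
            raise LibraryConfigError(f"token code must be a single character: {self.code!r}")
        if self.motif and len(self.motif) != 12:
            raise LibraryConfigError(
                f"motif for token {self.code!r} must be 12 bp, got {len(self.motif)}"
            )


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of site tokens plus pad / promoter / background codes."""

    tokens: tuple[SiteToken, ...]
    pad_code: str = PAD_CODE
    promoter_codes: tuple[str, ...] = ()
    background_codes: tuple[str, ...] = ()

    def __post_init__(self):
        codes = [t.code for t in self.tokens]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise LibraryConfigError(f"duplicate token codes: {dup}")

    @property
    def site_tokens(self) -> tuple[SiteToken, ...]:
        special = {self.pad_code, *self.promoter_codes, *self.background_codes}
        return tuple(t for t in self.tokens if t.code not in special)

    @property
    def site_codes(self) -> tuple[str, ...]:
        return tuple(t.code for t in self.site_tokens)

    def __getitem__(self, code: str) -> SiteToken:
        code = self.pad_code if code in PAD_ALIASES else code
        for t in self.tokens:
            if t.code == code:
                return t
        raise KeyError(f"code {code!r} not in alphabet")

    def __contains__(self, code: str) -> bool:
        try:
            self[code]
        except KeyError:
            return False
        return True


@dataclass(frozen=True)
class CREDesign:
    """An ordered 5'→3' arrangement of site codes upstream of a promoter."""

    sites: tuple[str, ...]
    promoter: str
    design_id: str = ""

    @property
    def token_string(self) -> str:
        return "".join(self.sites)


def _crx_nrl_tokens() -> list[SiteToken]:
    toks = []
    for aff, fwd, rev in [("high", "C", "c"), ("medium", "M", "m"), ("low", "L", "l")]:
        motif = MOTIFS[("CRX", aff)]
        toks.append(SiteToken(fwd, "CRX", aff, "forward", motif))
        toks.append(SiteToken(rev, "CRX", aff, "reverse", motif))
    # NRL consensus: sequence not in the CDNRM motif set; motif left empty.
    toks.append(SiteToken("N", "NRL", "high", "forward", ""))
    toks.append(SiteToken("n", "NRL", "high", "reverse", ""))
    toks.append(SiteToken(PAD_CODE, "special"))
    toks.append(SiteToken("R", "special"))  # Rho basal promoter
    toks.append(SiteToken("H", "special"))  # Hsp68 basal promoter
    return toks


def _cdnrm_tokens() -> list[SiteToken]:
    toks = [
        SiteToken("C", "CRX", "high", "forward", MOTIFS[("CRX", "high")]),
        SiteToken("c", "CRX", "medium", "forward", MOTIFS[("CRX", "medium")]),
        SiteToken("x", "CRX", "low", "forward", MOTIFS[("CRX", "low")]),
        SiteToken("D", "NEUROD1", "high", "forward", MOTIFS[("NEUROD1", "high")]),
        SiteToken("d", "NEUROD1", "medium", "forward", MOTIFS[("NEUROD1", "medium")]),
        SiteToken("N", "NRL", "high", "forward", MOTIFS[("NRL", "high")]),
        SiteToken("n", "NRL", "medium", "forward", MOTIFS[("NRL", "medium")]),
        SiteToken("R", "RORB", "high", "forward", MOTIFS[("RORB", "high")]),
        SiteToken("r", "RORB", "medium", "forward", MOTIFS[("RORB", "medium")]),
        SiteToken("M", "MAZ", "high", "forward", MOTIFS[("MAZ", "high")]),
        SiteToken("m", "MAZ", "medium", "forward", MOTIFS[("MAZ", "medium")]),
        SiteToken(PAD_CODE, "special"),
        SiteToken("P", "special"),  # Rho basal promoter ('R' is taken by RORB)
    ]
    return toks


def make_alphabet(library_spec="crx_nrl", tokens=None) -> Alphabet:
    """Build a site alphabet for a named library or from explicit tokens.

    Parameters
    ----------
    library_spec : {"crx_nrl", "cdnrm", "custom"}
        Named built-in library.  ``"custom"`` requires ``tokens``.
    tokens : sequence of SiteToken, optional
        Explicit token list for a custom alphabet.  Pad/promoter membership
        is inferred from ``tf == "special"`` only for built-ins; custom
        alphabets get the pad code and no promoters unless the caller
        constructs :class:`Alphabet` directly.
    """
    if library_spec == "crx_nrl":
        return Alphabet(tuple(_crx_nrl_tokens()), PAD_CODE, ("R", "H"))
    if library_spec == "cdnrm":
        return Alphabet(tuple(_cdnrm_tokens()), PAD_CODE, ("P",))
    if library_spec == "custom":
        if not tokens:
            raise LibraryConfigError("custom alphabet requires explicit tokens")
        return Alphabet(tuple(tokens), PAD_CODE, ())
    raise LibraryConfigError(f"unknown library spec {library_spec!r}")


def build_block(motif: str, pad: str = "") -> str:
    """Assemble the 20-bp building block ``AGCTAC<12-bp motif>GT``.

    Motifs are stored pre-padded as 12-mers; motifs shorter than 12 bp are
    only accepted together with an explicit ``pad`` string that brings the
    total to 12 (appended 3' of the motif).
    """
    seq = (motif + pad).upper()
    if any(ch not in "ACGT" for ch in seq):
        bad = sorted({ch for ch in seq if ch not in "ACGT"})
        raise ValueError(f"non-ACGT characters in motif: {bad}")
    if len(seq) != 12:
        raise ValueError(
            f"motif+pad must be exactly 12 bp (got {len(seq)}); "
            "supply an explicit pad for shorter motifs"
        )
    return BLOCK_PREFIX + seq + BLOCK_SUFFIX


def design_to_nucleotide(design: CREDesign, alphabet: Alphabet) -> str:
    """Concatenate each site's 20-bp building block, 5'→3'.

    Reverse-orientation tokens contribute the reverse complement of the
    forward block (flanks included), so the returned length is always
    ``20 * n_sites``.
    """
    parts = []
    for code in design.sites:
        tok = alphabet[code]
        if not tok.motif:
            raise ValueError(f"token {code!r} has no motif; cannot export nucleotides")
        block = build_block(tok.motif)
        if tok.orientation == "reverse":
            block = str(Seq(block).reverse_complement())
        parts.append(block)
    return "".join(parts)


def enumerate_exhaustive(site_codes, min_len: int, max_len: int) -> list[CREDesign]:
    """All ordered arrangements (repetition allowed) of lengths min..max.

    The count is sum over L of k**L for k site codes; for the 8-token
    CRX-NRL alphabet and lengths 1-3 this is 8 + 64 + 512 = 584.
    """
    site_codes = list(site_codes)
    if not site_codes:
        raise ValueError("empty site-token set")
    if min_len < 1 or max_len < min_len:
        raise ValueError("require 1 <= min_len <= max_len")
    designs = []
    for L in range(min_len, max_len + 1):
        for combo in itertools.product(site_codes, repeat=L):
            designs.append(CREDesign(tuple(combo), "", "".join(combo)))
    return designs


def sample_arrangements(site_codes, length: int, n: int, seed: int) -> list[CREDesign]:
    """Draw ``n`` distinct ordered arrangements of the given length.

    Uniform without replacement over all k**length arrangements;
    deterministic given ``seed``.
    """
    site_codes = list(site_codes)
    k = len(site_codes)
    if k == 0:
        raise ValueError("empty site-token set")
    total = k**length
    if n > total:
        raise ValueError(f"cannot draw {n} distinct arrangements from {total}")
    rng = np.random.default_rng(seed)
    idx = rng.choice(total, size=n, replace=False)
    designs = []
    for i in idx:
        digits = []
        v = int(i)
        for _ in range(length):
            digits.append(site_codes[v % k])
            v //= k
        sites = tuple(digits)  # base-k digits, 5'→3'
        designs.append(CREDesign(sites, "", "".join(sites)))
    return designs


def enumerate_composition_arrangements(composition: dict[str, int]) -> list[CREDesign]:
    """All distinct orderings of a multiset of site codes.

    ``composition`` maps code -> count; the number of arrangements is the
    multinomial coefficient (e.g. {C:3, D:1, R:1} -> 5!/3! = 20).
    """
    if not composition or sum(composition.values()) == 0:
        raise ValueError("empty composition")
    pool = [c for code, cnt in sorted(composition.items()) for c in [code] * cnt]
    designs = []
    for perm in multiset_permutations(pool):
        sites = tuple(perm)
        designs.append(CREDesign(sites, "", "".join(sites)))
    return designs


#: Default CRX-affinity multisets for the CDNRM designer: all-high or a
#: mixture of affinities, for three-CRX (3-1-1) and two-CRX (2-2-1) CREs.
DEFAULT_CRX_MIXTURES = (
    ("high", "high", "high"),
    ("high", "high", "medium"),
    ("high", "medium", "low"),
    ("high", "high"),
    ("high", "medium"),
    ("high", "low"),
)


def design_cdnrm_library(
    alphabet: Alphabet | None = None,
    crx_mixtures=DEFAULT_CRX_MIXTURES,
) -> list[CREDesign]:
    """Enumerate the CDNRM-style library of five-site, forward-only CREs.

    Each CRE combines CRX sites (affinity multisets per ``crx_mixtures``)
    with sites for other TFs in a 3-1-1 composition (three CRX, one site
    each for two other TFs) or 2-2-1 (two CRX, two sites of a second TF,
    one of a third).  The exact affinity-mixture rule of the original
    6,600-CRE library is not fully specified, so the total size depends on
    ``crx_mixtures`` and is reported, not asserted.
    """
    alphabet = alphabet or make_alphabet("cdnrm")
    by_tf_aff = {(t.tf, t.affinity): t.code for t in alphabet.site_tokens}
    other_tfs = ["NEUROD1", "NRL", "RORB", "MAZ"]
    other_affs = ["high", "medium"]
    designs: dict[str, CREDesign] = {}
    promoter = alphabet.promoter_codes[0]

    def add(composition):
        for d in enumerate_composition_arrangements(composition):
            d2 = CREDesign(d.sites, promoter, d.token_string)
            designs[d2.design_id] = d2

    three_crx = [m for m in crx_mixtures if len(m) == 3]
    two_crx = [m for m in crx_mixtures if len(m) == 2]
    # 3-1-1: three CRX sites + one site each for two distinct other TFs
    for mix in three_crx:
        crx_codes = [by_tf_aff[("CRX", a)] for a in mix]
        for tf1, tf2 in itertools.combinations(other_tfs, 2):
            for a1 in other_affs:
                for a2 in other_affs:
                    comp: dict[str, int] = {}
                    for c in crx_codes + [by_tf_aff[(tf1, a1)], by_tf_aff[(tf2, a2)]]:
                        comp[c] = comp.get(c, 0) + 1
                    add(comp)
    # 2-2-1: two CRX + two sites of a second TF + one site of a third
    for mix in two_crx:
        crx_codes = [by_tf_aff[("CRX", a)] for a in mix]
        for tf2, tf3 in itertools.permutations(other_tfs, 2):
            for a2 in other_affs:
                for a3 in other_affs:
                    comp = {}
                    for c in crx_codes + [by_tf_aff[(tf2, a2)]] * 2 + [by_tf_aff[(tf3, a3)]]:
                        comp[c] = comp.get(c, 0) + 1
                    add(comp)
    return list(designs.values())


def encode_fixed(design: CREDesign, target_len: int, alphabet: Alphabet) -> str:
    """Pad with 'O' to ``target_len`` sites and append the promoter code.

    ``sites [C, N], target_len 4, promoter R -> "OOCNR"``.  All encoded
    sequences of one dataset share length ``target_len + 1``.
    """
    n = len(design.sites)
    if n > target_len:
        raise ValueError(f"design has {n} sites, more than target length {target_len}")
    for code in design.sites:
        if code not in alphabet:
            raise KeyError(f"site code {code!r} not in alphabet")
    if design.promoter not in alphabet.promoter_codes:
        raise ValueError(f"promoter {design.promoter!r} not declared in alphabet")
    return alphabet.pad_code * (target_len - n) + design.token_string + design.promoter


def encode_binned(
    seq_length: int,
    sites: list[tuple[int, str]],
    bin_size: int = 9,
    background_code: str = "B",
) -> str:
    """Segment a nucleotide sequence into bins and encode one character per bin.

    A bin ``[bin_size*i, bin_size*i + bin_size)`` (0-based, half-open) gets
    the code of the site whose 5' start falls inside it, otherwise the
    background code.  Two site starts in one bin raise an error (sites in
    the source libraries are spaced >= 9 bp apart).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    n_bins = -(-seq_length // bin_size)  # ceil
    out = [background_code] * n_bins
    for start, code in sites:
        if not (0 <= start < seq_length):
            raise ValueError(f"site start {start} outside sequence of length {seq_length}")
        b = start // bin_size
        if out[b] != background_code:
            raise ValueError(f"two site starts fall in bin {b}; no tie rule is declared")
        out[b] = code
    return "".join(out)


def designs_to_table(designs, alphabet: Alphabet | None = None, target_len: int | None = None):
    """Tabulate designs as a DataFrame (design_id, token_string, promoter[, encoded_text])."""
    import pandas as pd

    rows = []
    for d in designs:
        row = {"design_id": d.design_id, "token_string": d.token_string, "promoter": d.promoter}
        if alphabet is not None and target_len is not None and d.promoter:
            row["encoded_text"] = encode_fixed(d, target_len, alphabet)
        rows.append(row)
    return pd.DataFrame(rows)


def designs_to_fasta(designs, alphabet: Alphabet, path) -> int:
    """Write nucleotide sequences of the designs as FASTA; returns record count."""
    from Bio import SeqIO
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(design_to_nucleotide(d, alphabet)), id=d.design_id or d.token_string,
                  description="")
        for d in designs
    ]
    return SeqIO.write(records, str(path), "fasta")
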