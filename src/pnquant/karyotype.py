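"""Parsing and classification of PGT karyotype result strings.

Blastocyst-biopsy PGT reports arrive as shorthand karyotype strings such
as ``"47, XN, +22(x3)"`` (whole-chromosome trisomy) or
``"46, XN, dup (16) (p13.3p13.13) (5.7 Mb)"`` (segmental duplication).
This module tokenises those strings into structured chromosome errors,
classifies each embryo into one of seven outcome categories, and — for
structural-rearrangement carriers (PGT-SR) — calls whether the embryo's
errors coincide with the parental rearrangement.

Category definitions (an error is *mosaic* when annotated mos/mosaic):

=====================  ====================================================
chromosome_normal      no errors (euploid, "46 XN")
sole_mosaic            every error is mosaic
sole_aneuploidy        only non-mosaic whole-chromosome gains/losses
sole_del_dup           only non-mosaic segmental deletions/duplications
euploidy_with_errors   segmental non-mosaic plus mosaic error(s), no
                       non-mosaic whole-chromosome error
aneuploidy_with_errors non-mosaic whole-chromosome error plus exactly one
                       other error class (segmental or mosaic)
complex                non-mosaic whole-chromosome + segmental + mosaic
=====================  ====================================================

``chromosome_normal`` and ``sole_mosaic`` together form the
"chromosome-normal" analysis group: sole mosaicism arises from mitotic
segregation errors after fertilisation and cannot be attributed to a
gamete.

The grammar is whitespace- and case-tolerant and accepts both ASCII and
the unicode variants that appear in clinical reports (minus sign,
multiplication sign, approx sign, arrow) as well as "m" or "Mb" for
megabases.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "CATEGORIES",
    "ChromError",
    "PGTResult",
    "PGTParseError",
    "parse_pgt_string",
    "classify",
    "analyze_pgt_string",
    "serialize_errors",
    "parental_rearranged_chromosomes",
    "parental_coincidence",
    "classify_normal_del_dup",
    "annotate_pgt_table",
]

CATEGORIES = (
    "chromosome_normal",
    "sole_mosaic",
    "sole_aneuploidy",
    "sole_del_dup",
    "euploidy_with_errors",
    "aneuploidy_with_errors",
    "complex",
)

NORMAL_GROUP_CATEGORIES = frozenset({"chromosome_normal", "sole_mosaic"})

_CHROMOSOMES = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


class PGTParseError(ValueError):
    """Raised on any token the grammar does not recognise."""


@dataclass(frozen=True)
class ChromError:
    """One chromosomal error.

    ``kind`` is ``gain``/``loss`` for whole-chromosome errors and
    ``dup``/``del`` for segmental ones; a band-range segment (with
    optional size in Mb) is present exactly for segmental errors.
    """

    chromosome: str
    kind: str  # gain | loss | dup | del
    segment: str | None = None
    size_mb: float | None = None
    mosaic: bool = False
    mosaic_pct: float | None = None

    def __post_init__(self) -> None:
        if self.chromosome not in _CHROMOSOMES:
            raise ValueError(f"bad chromosome {self.chromosome!r}")
        if self.kind not in ("gain", "loss", "dup", "del"):
            raise ValueError(f"bad kind {self.kind!r}")
        if (self.segment is not None) != (self.kind in ("dup", "del")):
            raise ValueError("segment must be present iff kind is dup/del")
        if self.size_mb is not None and self.size_mb <= 0:
            raise ValueError("size_mb must be positive")
        if self.mosaic_pct is not None:
            if not (0 < self.mosaic_pct < 100):
                raise ValueError("mosaic_pct must lie in (0, 100)")
            object.__setattr__(self, "mosaic", True)

    @property
    def is_whole_chromosome(self) -> bool:
        return self.kind in ("gain", "loss")

    @property
    def is_segmental(self) -> bool:
        return self.kind in ("dup", "del")


@dataclass
class PGTResult:
    raw: str
    errors: list[ChromError]
    category: str
    normal_group: bool = field(init=False)

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"bad category {self.category!r}")
        if (self.category == "chromosome_normal") != (len(self.errors) == 0):
            raise ValueError("chromosome_normal iff no errors")
        self.normal_group = self.category in NORMAL_GROUP_CATEGORIES


# ---------------------------------------------------------------------------
# Tokenisation

_UNICODE_MAP = str.maketrans({
    "−": "-",  # minus sign
    "–": "-",  # en dash
    "×": "x",  # multiplication sign
    "→": ">",  # rightwards arrow (band ranges like q42.12->qter)
    "≈": "",   # approx sign
    "~": "",
    " ": " ",
})


def _normalise(raw: str) -> str:
    return " ".join(raw.translate(_UNICODE_MAP).split())


def _split_top_level(s: str) -> list[str]:
    """Split on commas that are not inside parentheses."""
    parts, depth, cur = [], 0, []
    for ch in s:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth = max(0, depth - 1)
        if ch == "," and depth == 0:
            parts.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    parts.append("".join(cur).strip())
    return [p for p in parts if p]


_CHROM = r"(?:\d{1,2}|X|Y)"

# "46 XN", "46XN", "47", "XN", "45,XN" prefix pieces
_PREFIX_RE = re.compile(rf"^(?:\d{{2}})?\s*(?:X[NXY])?$", re.IGNORECASE)

# +22(x3), +22, (x3) optional copy count
_WHOLE_GAIN_RE = re.compile(
    rf"^\+\s*({_CHROM})\s*(?:\(\s*x\s*(\d+)\s*\))?$", re.IGNORECASE
)
# (-21), -21
_WHOLE_LOSS_RE = re.compile(rf"^\(?\s*-\s*({_CHROM})\s*\)?$", re.IGNORECASE)
# + mosaic (22) (33%) / -mosaic (22) (33%) / mos (22) (33%)
_WHOLE_MOSAIC_RE = re.compile(
    rf"^([+-])?\s*mos(?:aic)?\s*\(\s*({_CHROM})\s*\)\s*\(\s*(\d+(?:\.\d+)?)\s*%\s*\)$",
    re.IGNORECASE,
)
# dup (16) (p13.3p13.13) (5.7 Mb) [(mos, 50%)]
_SEG_NAMED_RE = re.compile(
    rf"^(dup|del)\s*\(\s*({_CHROM})\s*\)\s*\(\s*([^)]+?)\s*\)"
    rf"\s*(?:\(\s*(\d+(?:\.\d+)?)\s*(?:Mb|m|kb)\s*\))?"
    rf"\s*(?:\(\s*mos(?:aic)?\s*(?:,\s*(\d+(?:\.\d+)?)\s*%)?\s*\))?$",
    re.IGNORECASE,
)
# +4q (q12q31.1, 89 Mb, x3) / 9p (p20p21.1, 32 Mb, x1, mos, 50%)
_SEG_ARM_RE = re.compile(
    rf"^([+-])?\s*({_CHROM})\s*([pq])\s*\(\s*(.+)\s*\)$", re.IGNORECASE
)


def _parse_arm_attrs(chrom: str, sign: str | None, arm: str, inner: str) -> ChromError:
    attrs = [a.strip() for a in inner.split(",") if a.strip()]
    band: str | None = None
    size_mb: float | None = None
    copies: int | None = None
    mosaic = False
    mosaic_pct: float | None = None
    for a in attrs:
        m = re.fullmatch(r"x\s*(\d+)", a, re.IGNORECASE)
        if m:
            copies = int(m.group(1))
            continue
        m = re.fullmatch(r"(\d+(?:\.\d+)?)\s*(Mb|m|kb)", a, re.IGNORECASE)
        if m:
            size_mb = float(m.group(1))
            if m.group(2).lower() == "kb":
                size_mb /= 1000.0
            continue
        if re.fullmatch(r"mos(?:aic)?", a, re.IGNORECASE):
            mosaic = True
            continue
        m = re.fullmatch(r"(\d+(?:\.\d+)?)\s*%", a, re.IGNORECASE)
        if m:
            mosaic_pct = float(m.group(1))
            continue
        if re.fullmatch(r"[pq][\dpq.>ter]*(?:[pq\d.>]|ter)?", a, re.IGNORECASE) and band is None:
            band = a
            continue
        raise PGTParseError(f"unrecognised segment attribute {a!r}")
    if band is None:
        raise PGTParseError(f"segmental error on {chrom}{arm} lacks a band range: {inner!r}")
    if copies is not None:
        kind = "dup" if copies >= 3 else "del" if copies <= 1 else "dup"
    elif sign is not None:
        kind = "dup" if sign == "+" else "del"
    else:
        raise PGTParseError(
            f"cannot infer dup/del for {chrom}{arm}({inner}): no copy count or sign"
        )
    if mosaic_pct is not None:
        mosaic = True
    return ChromError(chrom, kind, segment=band, size_mb=size_mb,
                      mosaic=mosaic, mosaic_pct=mosaic_pct)


def _norm_chrom(c: str) -> str:
    c = c.upper()
    return c if c in ("X", "Y") else str(int(c))


def parse_pgt_string(raw: str) -> list[ChromError]:
    """Parse a PGT result string into a list of :class:`ChromError`.

    The euploid prefix (``"46 XN"`` and variants) parses to an empty
    list.  Any token the grammar cannot place raises
    :class:`PGTParseError` naming the token — unknown notation is never
    silently skipped.
    """
    if not raw or not raw.strip():
        raise PGTParseError("empty PGT string")
    tokens = _split_top_level(_normalise(raw))
    errors: list[ChromError] = []
    for i, tok in enumerate(tokens):
        # ploidy/sex prefix tokens may only open the string
        if i <= 1 and _PREFIX_RE.fullmatch(tok) and not errors:
            continue
        m = _WHOLE_MOSAIC_RE.fullmatch(tok)
        if m:
            sign, chrom, pct = m.groups()
            kind = "loss" if sign == "-" else "gain"
            errors.append(ChromError(_norm_chrom(chrom), kind, mosaic_pct=float(pct)))
            continue
        m = _WHOLE_GAIN_RE.fullmatch(tok)
        if m:
            chrom, copies = m.groups()
            kind = "gain" if copies is None or int(copies) >= 3 else "loss"
            errors.append(ChromError(_norm_chrom(chrom), kind))
            continue
        m = _WHOLE_LOSS_RE.fullmatch(tok)
        if m:
            errors.append(ChromError(_norm_chrom(m.group(1)), "loss"))
            continue
        m = _SEG_NAMED_RE.fullmatch(tok)
        if m:
            kind, chrom, band, size, pct = m.groups()
            mos = "mos" in tok.lower()
            errors.append(
                ChromError(
                    _norm_chrom(chrom),
                    kind.lower(),
                    segment=band,
                    size_mb=float(size) if size else None,
                    mosaic=mos,
                    mosaic_pct=float(pct) if pct else None,
                )
            )
            continue
        m = _SEG_ARM_RE.fullmatch(tok)
        if m:
            sign, chrom, arm, inner = m.groups()
            errors.append(_parse_arm_attrs(_norm_chrom(chrom), sign, arm.lower(), inner))
            continue
        raise PGTParseError(f"unrecognised token {tok!r} in {raw!r}")
    return errors


# ---------------------------------------------------------------------------
# Classification


def classify(errors: Sequence[ChromError]) -> str:
    """Assign one of the seven outcome categories to a parsed error list.

    Total and deterministic: every possible error list lands in exactly
    one category.
    """
    if not errors:
        return "chromosome_normal"
    if all(e.mosaic for e in errors):
        return "sole_mosaic"
    nm_whole = any(e.is_whole_chromosome and not e.mosaic for e in errors)
    nm_seg = any(e.is_segmental and not e.mosaic for e in errors)
    any_mosaic = any(e.mosaic for e in errors)
    if nm_whole:
        if nm_seg and any_mosaic:
            return "complex"
        if nm_seg or any_mosaic:
            return "aneuploidy_with_errors"
        return "sole_aneuploidy"
    # no non-mosaic whole-chromosome error below this line
    if nm_seg and any_mosaic:
        return "euploidy_with_errors"
    return "sole_del_dup"


def analyze_pgt_string(raw: str) -> PGTResult:
    """Parse and classify in one call."""
    errors = parse_pgt_string(raw)
    return PGTResult(raw=raw, errors=errors, category=classify(errors))


def serialize_errors(errors: Sequence[ChromError]) -> str:
    """Render errors back to a canonical report string.

    ``parse -> serialize -> parse`` is a fixed point: re-parsing the
    canonical form recovers the identical error list.
    """
    net = sum(
        (1 if e.kind == "gain" else -1)
        for e in errors
        if e.is_whole_chromosome and not e.mosaic
    )
    parts = [f"{46 + net}", "XN"]
    for e in errors:
        if e.is_whole_chromosome:
            if e.mosaic:
                sign = "+" if e.kind == "gain" else "-"
                parts.append(f"{sign}mosaic ({e.chromosome}) ({e.mosaic_pct:.12g}%)")
            elif e.kind == "gain":
                parts.append(f"+{e.chromosome}(x3)")
            else:
                parts.append(f"(-{e.chromosome})")
        else:
            tok = f"{e.kind} ({e.chromosome}) ({e.segment})"
            if e.size_mb is not None:
                tok += f" ({e.size_mb:.12g} Mb)"
            if e.mosaic:
                tok += f" (mos, {e.mosaic_pct:.12g}%)" if e.mosaic_pct else " (mos)"
            parts.append(tok)
    return ", ".join(parts)


# ---------------------------------------------------------------------------
# Parental coincidence (PGT-SR)

_REARRANGEMENT_RE = re.compile(
    r"\b(?:t|rob|der|inv|ins|dup|del)\s*\(\s*([0-9XY;,\s]+)\s*\)", re.IGNORECASE
)


def parental_rearranged_chromosomes(parental_karyotype: str) -> frozenset[str]:
    """Chromosomes involved in a parent's structural rearrangement.

    ``"46, XX, t(1,16)(q42:q12)"`` -> ``{"1", "16"}``.  Raises
    :class:`PGTParseError` when no rearrangement can be read.
    """
    s = _normalise(parental_karyotype)
    chroms: set[str] = set()
    for m in _REARRANGEMENT_RE.finditer(s):
        for piece in re.split(r"[;,\s]+", m.group(1)):
            if piece and re.fullmatch(_CHROM, piece, re.IGNORECASE):
                chroms.add(_norm_chrom(piece))
    if not chroms:
        raise PGTParseError(
            f"no rearranged chromosomes found in parental karyotype {parental_karyotype!r}"
        )
    return frozenset(chroms)


def parental_coincidence(
    embryo: PGTResult | str, parental_karyotype: str, propositus: str = "female"
) -> str:
    """Call embryo errors coincident/inconsistent with the carrier parent.

    Resolution is at chromosome level: *coincident* when any embryo error
    involves a chromosome of the parental rearranged set, *inconsistent*
    when the embryo has errors but none overlap, *not_applicable* for
    chromosome-normal or sole-mosaic embryos (mosaicism is mitotic and
    cannot be inherited from a gamete).
    """
    if propositus not in ("female", "male"):
        raise ValueError(f"propositus must be female or male, got {propositus!r}")
    if isinstance(embryo, str):
        embryo = analyze_pgt_string(embryo)
    if not embryo.errors or embryo.category == "sole_mosaic":
        return "not_applicable"
    parental = parental_rearranged_chromosomes(parental_karyotype)
    hit = any(e.chromosome in parental for e in embryo.errors)
    return "coincident" if hit else "inconsistent"


def classify_normal_del_dup(errors: Sequence[ChromError]) -> str:
    """Alternative trichotomous labeling: normal / deletion / duplication.

    An earlier outcome design grouped embryos by the direction of copy
    change only.  Mixed-direction embryos label ``"both"``.  Not used by
    the default statistics.
    """
    if not errors:
        return "normal"
    has_dup = any(e.kind in ("gain", "dup") for e in errors)
    has_del = any(e.kind in ("loss", "del") for e in errors)
    if has_dup and has_del:
        return "both"
    return "duplication" if has_dup else "deletion"


def annotate_pgt_table(df: pd.DataFrame) -> pd.DataFrame:
    """Annotate a PGT CSV table with category/normal_group/coincidence.

    Expects columns ``embryo_id, pgt_string`` and optionally
    ``patient_id, propositus, parental_karyotype``.
    """
    if "pgt_string" not in df.columns:
        raise ValueError("table must have a pgt_string column")
    out = df.copy()
    results = [analyze_pgt_string(s) for s in out["pgt_string"]]
    out["category"] = [r.category for r in results]
    out["normal_group"] = [r.normal_group for r in results]
    if "parental_karyotype" in out.columns:
        calls = []
        for r, (_, row) in zip(results, out.iterrows()):
            prop = row.get("propositus", "none")
            kar = row.get("parental_karyotype", None)
            if prop in ("female", "male") and isinstance(kar, str) and kar.strip():
                calls.append(parental_coincidence(r, kar, prop))
            else:
                calls.append("not_applicable")
        out["coincidence"] = calls
    return out
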