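"""Histone PTM relative abundance and variant stoichiometry from peptide intensities.

Bottom-up histone MS yields one intensity per (sample, peptide backbone,
modification form). Two quantities are derived here:

* **PTM relative abundance** — the intensity of a modified peptide form divided
  by the summed intensity of all modified and unmodified forms sharing the same
  backbone sequence (its *peptide family*).

* **Variant stoichiometry** — variant-specific peptide intensities normalized to
  reference peptides whose sequence is shared across a histone family, so that
  each ratio estimates "copies of variant V per total family copy". For the
  H2A family there are four reference peptides and three variant-specific
  peptides (canonical H2A, H2A.Z, macroH2A); for the H3 family the
  canonical-H3 (H3.1/H3.2) and H3.3 forms of the 27-40 peptide differ by a
  single residue (A31 vs S31) and are compared directly. H3.1 and H3.2 share
  every tryptic peptide used and are merged throughout.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REFERENCE_PEPTIDES",
    "PTM_SITES",
    "PeptideFamily",
    "VariantFractions",
    "canonical_mods",
    "build_families",
    "ptm_relative_abundance",
    "log2_enrichment",
    "h2a_variant_fractions",
    "h3_variant_fractions",
]

# Fixed quantification peptides: name -> (histone, span_start, span_end, sequence).
# Spans are 1-based inclusive residue coordinates on the mature protein.
REFERENCE_PEPTIDES: dict[str, tuple[str, int, int, str]] = {
    "H2Ac_1": ("H2A", 4, 11, "GKQGGKAR"),
    "H2Ac_2": ("H2A", 12, 17, "AKAKTR"),
    "H2Ac_3": ("H2A", 21, 29, "AGLQFPVGR"),
    "H2Ac_4": ("H2A", 82, 88, "HLQLAIR"),
    "H2A_canonical": ("H2A", 36, 42, "KGNYAER"),
    "macroH2A": ("macroH2A", 4, 14, "GGKKKSTKTSR"),
    "H2A.Z": ("H2A.Z", 1, 19, "AGGKAGKDSGKAKTKAVSR"),
    "H3_canonical_27_40": ("H3", 27, 40, "KSAPATGGVKKPHR"),
    "H3.3_27_40": ("H3", 27, 40, "KSAPSTGGVKKPHR"),
}

H2A_REFERENCE_NAMES = ("H2Ac_1", "H2Ac_2", "H2Ac_3", "H2Ac_4")

# Residue -> peptide span housing it, per histone. Used to locate the family a
# mark is quantified on and by the synthetic forward model.
PTM_SITES: dict[str, dict[int, tuple[int, int]]] = {
    "H3": {4: (3, 8), 9: (9, 17), 14: (9, 17), 18: (18, 26), 23: (18, 26),
           27: (27, 40), 36: (27, 40)},
    "H4": {5: (4, 17), 8: (4, 17), 12: (4, 17), 16: (4, 17)},
}

# Shared tail peptides used for PTM quantification (sequence identical across
# variants of the family): histone -> span -> sequence.
PTM_PEPTIDES: dict[str, dict[tuple[int, int], str]] = {
    "H3": {(3, 8): "TKQTAR", (9, 17): "KSTGGKAPR", (18, 26): "KQLATKAAR"},
    "H4": {(4, 17): "GKGGKGLGKGGAKR"},
}

_MOD_TOKEN = re.compile(r"([A-Z])(\d+)((?:me[123])|ac|ph|ub)")


def parse_mark(mark: str) -> tuple[str, list[tuple[str, int, str]]]:
    """Split a mark like ``"H3K27me3"`` or ``"H4K5acK8ac"`` into
    (histone, [(residue-letter, position, mod), ...])."""
    m = re.match(r"(H2A\.Z|macroH2A|H2A|H2B|H3|H4)", mark)
    if not m:
        raise ValueError(f"cannot parse histone from mark {mark!r}")
    histone = m.group(1)
    tokens = _MOD_TOKEN.findall(mark[m.end():])
    if not tokens:
        raise ValueError(f"no modification tokens in mark {mark!r}")
    return histone, [(aa, int(pos), mod) for aa, pos, mod in tokens]


def canonical_mods(mods: str) -> str:
    """Canonicalize a modification string: tokens sorted by residue position.

    The empty string denotes the unmodified form.
    """
    if not mods:
        return ""
    tokens = _MOD_TOKEN.findall(mods)
    joined = "".join(f"{aa}{pos}{mod}" for aa, pos, mod in tokens)
    if joined != mods.replace(" ", ""):
        raise ValueError(f"unparseable modification string {mods!r}")
    return "".join(f"{aa}{pos}{mod}"
                   for aa, pos, mod in sorted(tokens, key=lambda t: (int(t[1]), t[2])))


def _mod_tokens(mods: str) -> set[str]:
    return {f"{aa}{pos}{mod}" for aa, pos, mod in _MOD_TOKEN.findall(mods)}


@dataclass
class PeptideFamily:
    """All modified + unmodified forms of one backbone in one sample."""

    sample: str
    histone: str
    span: tuple[int, int]
    sequence: str
    forms: dict[str, float] = field(default_factory=dict)  # mods -> intensity

    @property
    def total(self) -> float:
        return float(sum(self.forms.values()))

    @property
    def key(self) -> tuple[str, str, tuple[int, int], str]:
        return (self.sample, self.histone, self.span, self.sequence)


@dataclass
class VariantFractions:
    """Per-sample stoichiometry of one histone family (fractions sum to 1)."""

    sample_id: str
    family: str  # "H2A-family" | "H3-family"
    fractions: dict[str, float]
    per_reference_ratios: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"fractions sum to {total}, expected 1")
        if any(f < -1e-12 for f in self.fractions.values()):
            raise ValueError("negative variant fraction")


PEPTIDE_COLUMNS = ["sample", "histone", "span_start", "span_end",
                   "sequence", "mods", "intensity"]


def build_families(table: pd.DataFrame) -> list[PeptideFamily]:
    """Partition peptide records into families keyed by
    (sample, histone, span, sequence); duplicate records are summed.

    ``table`` must carry the columns sample, histone, span_start, span_end,
    sequence, mods, intensity. Negative intensities are rejected.
    """
    missing = [c for c in PEPTIDE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peptide table missing columns: {missing}")
    if (table["intensity"] < 0).any():
        bad = table[table["intensity"] < 0].index[0]
        raise ValueError(f"negative intensity at row {bad}")

    families: dict[tuple, PeptideFamily] = {}
    for row in table.itertuples(index=False):
        mods = canonical_mods("" if pd.isna(row.mods) else str(row.mods))
        span = (int(row.span_start), int(row.span_end))
        key = (row.sample, row.histone, span, row.sequence)
        fam = families.get(key)
        if fam is None:
            fam = families[key] = PeptideFamily(row.sample, row.histone, span,
                                                row.sequence)
        fam.forms[mods] = fam.forms.get(mods, 0.0) + float(row.intensity)
    return list(families.values())


def _families_by_sample(families) -> dict[str, list[PeptideFamily]]:
    out: dict[str, list[PeptideFamily]] = {}
    for fam in families:
        out.setdefault(fam.sample, []).append(fam)
    return out


def ptm_relative_abundance(families, marks: list[str] | None = None) -> pd.DataFrame:
    """Relative abundance of single marks and combinatorial forms.

    For a single mark the numerator sums every form carrying the mark
    (co-modified forms included); for a combination (two or more tokens)
    the form must match exactly. The denominator is the summed intensity of
    all forms of every family matching the mark's (histone, span) in that
    sample — families that differ only in a variant-discriminating residue
    (e.g. the two 27-40 H3 backbones) are aggregated, since the mark itself
    is not variant-specific.

    Returns a tidy frame (sample, mark, kind, abundance). ``marks`` defaults
    to every mark token and every multi-token combination observed. Marks
    whose family is absent in a sample are omitted (missing, not zero).
    """
    by_sample = _families_by_sample(families)
    rows = []
    for sample, fams in sorted(by_sample.items()):
        if marks is None:
            singles: set[str] = set()
            combos: set[str] = set()
            for fam in fams:
                for mods in fam.forms:
                    toks = _mod_tokens(mods)
                    singles.update(f"{fam.histone}{t}" for t in toks)
                    if len(toks) > 1:
                        combos.add(f"{fam.histone}{mods}")
            wanted = sorted(singles) + sorted(combos)
        else:
            wanted = marks
        for mark in wanted:
            histone, tokens = parse_mark(mark)
            sites = PTM_SITES.get(histone, {})
            spans = {sites.get(pos) for _, pos, _ in tokens}
            if len(spans) != 1 or None in spans:
                raise ValueError(
                    f"mark {mark!r} does not map to a single quantification peptide")
            span = spans.pop()
            matched = [f for f in fams if f.histone == histone and f.span == span]
            if not matched:
                continue  # reported as missing, not zero
            denom = sum(f.total for f in matched)
            if denom <= 0:
                raise ValueError(f"family total is zero for mark {mark!r} "
                                 f"in sample {sample!r}")
            want = {f"{aa}{pos}{mod}" for aa, pos, mod in tokens}
            kind = "single" if len(want) == 1 else "combination"
            num = 0.0
            for fam in matched:
                for mods, inten in fam.forms.items():
                    have = _mod_tokens(mods)
                    if (want <= have) if kind == "single" else (want == have):
                        num += inten
            rows.append((sample, mark, kind, num / denom))
    return pd.DataFrame(rows, columns=["sample", "mark", "kind", "abundance"])


def log2_enrichment(ip: pd.DataFrame, input_: pd.DataFrame,
                    pseudocount: float = 1e-4) -> pd.DataFrame:
    """log2((a_IP + p) / (a_input + p)) per (IP sample, mark).

    Both frames are outputs of :func:`ptm_relative_abundance`; the input frame
    must contain a single sample. Returns (sample, mark, kind, log2_ratio,
    pseudocount). Marks with zero abundance in both arms map to exactly 0.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    if input_["sample"].nunique() != 1:
        raise ValueError("input table must contain exactly one sample")
    merged = ip.merge(input_[["mark", "kind", "abundance"]],
                      on=["mark", "kind"], suffixes=("_ip", "_in"))
    if merged.empty:
        raise ValueError("no shared (mark, kind) keys between IP and input")
    a_ip = merged["abundance_ip"].to_numpy(float)
    a_in = merged["abundance_in"].to_numpy(float)
    ratio = np.log2((a_ip + pseudocount) / (a_in + pseudocount))
    ratio[(a_ip == 0) & (a_in == 0)] = 0.0
    out = merged[["sample", "mark", "kind"]].copy()
    out["log2_ratio"] = ratio
    out["pseudocount"] = pseudocount
    return out


def _family_total(fams: list[PeptideFamily], sequence: str) -> float | None:
    """Summed intensity over all modified forms of the family with this backbone."""
    totals = [f.total for f in fams if f.sequence == sequence]
    if not totals:
        return None
    return float(sum(totals))


def h2a_variant_fractions(families, allow_missing: bool = False
                          ) -> dict[str, VariantFractions]:
    """H2A-family stoichiometry per sample.

    Each variant-specific peptide (canonical H2A KGNYAER, H2A.Z 1-19,
    macroH2A 4-14) is ratioed against each of the four H2A reference peptides;
    the four ratios are averaged (arithmetic mean) into one summary ratio per
    variant, and the summaries are renormalized to sum to 1. Raw per-reference
    ratios are retained for QC.

    A missing variant peptide is an error unless ``allow_missing``, in which
    case the variant is treated as absent (ratio 0). A reference family with
    zero total is always an error.
    """
    variants = {"H2A": "H2A_canonical", "H2A.Z": "H2A.Z", "macroH2A": "macroH2A"}
    out: dict[str, VariantFractions] = {}
    for sample, fams in sorted(_families_by_sample(families).items()):
        ref_totals = {}
        for name in H2A_REFERENCE_NAMES:
            seq = REFERENCE_PEPTIDES[name][3]
            tot = _family_total(fams, seq)
            if tot is None or tot <= 0:
                raise ValueError(
                    f"reference peptide {name} absent or zero in sample {sample!r}")
            ref_totals[name] = tot
        per_ref: dict[tuple[str, str], float] = {}
        summary: dict[str, float] = {}
        for variant, pep in variants.items():
            seq = REFERENCE_PEPTIDES[pep][3]
            tot = _family_total(fams, seq)
            if tot is None:
                if not allow_missing:
                    raise ValueError(f"variant peptide for {variant} missing in "
                                     f"sample {sample!r} (allow_missing=False)")
                tot = 0.0
            ratios = [tot / ref_totals[name] for name in H2A_REFERENCE_NAMES]
            for name, r in zip(H2A_REFERENCE_NAMES, ratios):
                per_ref[(variant, name)] = r
            summary[variant] = float(np.mean(ratios))
        total = sum(summary.values())
        if total <= 0:
            raise ValueError(f"all variant ratios zero in sample {sample!r}")
        fractions = {v: r / total for v, r in summary.items()}
        out[sample] = VariantFractions(sample, "H2A-family", fractions, per_ref)
    return out


def h3_variant_fractions(families) -> dict[str, VariantFractions]:
    """H3-family stoichiometry per sample from the 27-40 peptide pair.

    fraction(H3.3) = I(H3.3 27-40) / (I(canonical 27-40) + I(H3.3 27-40));
    canonical H3 is the merged H3.1+H3.2 (indistinguishable by this peptide).
    Family totals sum all modified forms. Both totals zero is an error.
    """
    seq_can = REFERENCE_PEPTIDES["H3_canonical_27_40"][3]
    seq_33 = REFERENCE_PEPTIDES["H3.3_27_40"][3]
    out: dict[str, VariantFractions] = {}
    for sample, fams in sorted(_families_by_sample(families).items()):
        i_can = _family_total(fams, seq_can) or 0.0
        i_33 = _family_total(fams, seq_33) or 0.0
        if i_can + i_33 <= 0:
            raise ValueError(f"both H3 27-40 totals zero in sample {sample!r}")
        f33 = i_33 / (i_can + i_33)
        out[sample] = VariantFractions(
            sample, "H3-family", {"H3": 1.0 - f33, "H3.3": f33},
            {("H3.3", "H3_canonical_27_40"): (i_33 / i_can if i_can else math.inf)})
    return out
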