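"""Plain-text interchange formats: MARK .inp encounter histories and
GenePop genotype files.

The .inp dialect written here is the classic RMark-compatible layout:
an optional ``/* comment */`` with the individual id, the binary
encounter history, one frequency column per group (JuvU, JuvR), then
two individual covariates (family-unit flag and body condition), each
record terminated by a semicolon. GenePop files use 2- or 3-digit
allele codes, ``0`` codes meaning missing.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np

from .cmr import EncounterHistory
from .kinship import AlleleFrequencies

__all__ = ["write_inp", "read_inp", "write_genepop", "read_genepop"]

GROUPS = ("JuvU", "JuvR")


def write_inp(histories, path) -> None:
    lines = []
    for h in histories:
        gcols = " ".join("1" if h.group == g else "0" for g in GROUPS)
        cond = 0.0 if h.body_condition is None else h.body_condition
        hist = "".join(str(int(x)) for x in h.history)
        lines.append(f"/* {h.individual_id} */ {hist} {gcols} "
                     f"{int(h.born_in_family_unit)} {cond:.6f};")
    Path(path).write_text("\n".join(lines) + "\n")


_INP_RE = re.compile(
    r"(?:/\*\s*(?P<id>\S+)\s*\*/\s*)?(?P<hist>[01]+)\s+(?P<rest>[^;]*);")


def read_inp(path) -> list[EncounterHistory]:
    out = []
    text = Path(path).read_text()
    for i, m in enumerate(_INP_RE.finditer(text)):
        rest = m.group("rest").split()
        if len(rest) < len(GROUPS):
            raise ValueError(f"record {i}: missing group frequency columns")
        gvals = [int(float(v)) for v in rest[:len(GROUPS)]]
        if sum(gvals) != 1:
            raise ValueError(f"record {i}: exactly one group column must be 1")
        group = GROUPS[gvals.index(1)]
        fam = bool(int(float(rest[len(GROUPS)]))) if len(rest) > len(GROUPS) else False
        cond = float(rest[len(GROUPS) + 1]) if len(rest) > len(GROUPS) + 1 else None
        out.append(EncounterHistory(
            individual_id=m.group("id") or f"ind_{i}",
            history=np.array([int(c) for c in m.group("hist")]),
            group=group, born_in_family_unit=fam, body_condition=cond))
    if not out:
        raise ValueError(f"no records parsed from {path}")
    return out


def _code_width(loci_alleles) -> int:
    return 3 if any(int(a) > 99 for a in loci_alleles) else 2


def write_genepop(genotypes: dict, path, title: str = "owlfam genotypes") -> None:
    """``genotypes``: individual -> {locus: (a1, a2) or None}."""
    if not genotypes:
        raise ValueError("empty genotype table")
    loci = list(next(iter(genotypes.values())))
    alleles = [a for g in genotypes.values() for pair in g.values()
               if pair is not None for a in pair]
    w = _code_width(alleles)
    lines = [title] + loci + ["Pop"]
    for ind, g in genotypes.items():
        codes = []
        for loc in loci:
            pair = g.get(loc)
            if pair is None:
                codes.append("0" * (2 * w))
            else:
                codes.append(f"{int(pair[0]):0{w}d}{int(pair[1]):0{w}d}")
        lines.append(f"{ind} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(lines) + "\n")


def read_genepop(path) -> dict:
    lines = [ln.rstrip() for ln in Path(path).read_text().splitlines()
             if ln.strip()]
    if len(lines) < 3:
        raise ValueError("truncated GenePop file")
    loci: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        # locus names may be one per line or comma-separated
        loci.extend(s.strip() for s in lines[i].split(",") if s.strip())
        i += 1
    if i == len(lines):
        raise ValueError("no 'Pop' line found")
    out: dict = {}
    for ln in lines[i + 1:]:
        if ln.strip().lower() == "pop":
            continue
        if "," not in ln:
            raise ValueError(f"malformed individual line: {ln!r}")
        ind, codes = ln.split(",", 1)
        codes = codes.split()
        if len(codes) != len(loci):
            raise ValueError(f"{ind.strip()}: {len(codes)} genotypes for "
                             f"{len(loci)} loci")
        g = {}
        for loc, code in zip(loci, codes):
            w = len(code) // 2
            a1, a2 = int(code[:w]), int(code[w:])
            g[loc] = None if a1 == 0 or a2 == 0 else (a1, a2)
        out[ind.strip()] = g
    if not out:
        raise ValueError("no individuals parsed")
    return out
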