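"""Tiny atom-selection language: conjunctions and unions of simple predicates.

Grammar (whitespace-separated, case-insensitive keywords)::

    expr  := term { "or" term }
    term  := prim { "and" prim }
    prim  := "all" | "protein" | "substrate"
           | "resid" N | "resid" N-M
           | "resname" NAME[,NAME...]
           | "chain" C
           | "type" (aha|hmd|none)

Examples: ``"resid 138-140"``, ``"substrate and type aha"``,
``"chain A or chain B"``. Evaluation against a structure yields a sorted,
deterministic atom-index list.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

from .errors import SelectionError
from .io_formats import AtomRecord, Structure, SubstrateType

__all__ = ["AtomSelection", "select"]

_Pred = Callable[[AtomRecord], bool]


def _parse_prim(tokens: list[str]) -> _Pred:
    if not tokens:
        raise SelectionError("empty selection term")
    kw = tokens[0].lower()
    args = tokens[1:]
    if kw == "all":
        return lambda a: True
    if kw == "protein":
        return lambda a: a.is_protein
    if kw == "substrate":
        return lambda a: a.substrate_type is not SubstrateType.NONE
    if kw == "resid":
        if len(args) != 1:
            raise SelectionError(f"resid takes one argument, got {args!r}")
        spec = args[0]
        try:
            if "-" in spec[1:]:
                cut = spec.index("-", 1)
                lo, hi = int(spec[:cut]), int(spec[cut + 1:])
            else:
                lo = hi = int(spec)
        except ValueError:
            raise SelectionError(f"bad resid argument {spec!r}") from None
        if hi < lo:
            raise SelectionError(f"bad resid range {spec!r}")
        return lambda a: lo <= a.residue_number <= hi
    if kw == "resname":
        if not args:
            raise SelectionError("resname needs at least one name")
        names = {n.upper() for arg in args for n in arg.split(",") if n}
        return lambda a: a.residue_name.upper() in names
    if kw == "chain":
        if len(args) != 1:
            raise SelectionError(f"chain takes one argument, got {args!r}")
        c = args[0]
        return lambda a: a.chain_id == c
    if kw == "type":
        if len(args) != 1:
            raise SelectionError(f"type takes one argument, got {args!r}")
        try:
            st = SubstrateType(args[0].lower())
        except ValueError:
            raise SelectionError(f"unknown substrate type {args[0]!r}") from None
        return lambda a: a.substrate_type is st
    raise SelectionError(f"unknown selection keyword {kw!r}")


def _split_on(tokens: list[str], sep: str) -> list[list[str]]:
    out: list[list[str]] = [[]]
    for t in tokens:
        if t.lower() == sep:
            out.append([])
        else:
            out[-1].append(t)
    return out


@dataclass(frozen=True)
class AtomSelection:
    """A compiled selection expression; evaluate with :meth:`indices`."""

    expression: str

    def _predicate(self) -> _Pred:
        tokens = self.expression.split()
        if not tokens:
            raise SelectionError("empty selection expression")
        terms = _split_on(tokens, "or")
        compiled_terms: list[list[_Pred]] = []
        for term in terms:
            prims = _split_on(term, "and")
            compiled_terms.append([_parse_prim(p) for p in prims])
        return lambda a: any(all(p(a) for p in prims) for prims in compiled_terms)

    def indices(self, structure: Structure) -> list[int]:
        """Sorted atom indices matching this selection (may be empty)."""
        pred = self._predicate()
        return [i for i, a in enumerate(structure.atoms) if pred(a)]


def select(structure: Structure, expression: str | AtomSelection) -> list[int]:
    """Evaluate ``expression``; raise :class:`SelectionError` if it matches nothing."""
    sel = expression if isinstance(expression, AtomSelection) else AtomSelection(expression)
    idx = sel.indices(structure)
    if not idx:
        raise SelectionError(f"selection {sel.expression!r} matches no atoms")
    return idx
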