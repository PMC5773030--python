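"""A minimal timed parametric L-system engine.

Modules are symbols with real-valued parameters; a derivation step rewrites
every module in parallel using the first production whose symbol and
condition match, advancing a global clock by ``dt`` each step.  Modules with
no matching production persist; if the grammar declares an age parameter
for their symbol (the ``aging`` map), that parameter is advanced by ``dt``.

The text form round-trips: ``A(3)[&(40)L(5,0.7)]``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Callable, Iterable, Optional, Sequence

__all__ = [
    "ModuleInstance",
    "Production",
    "GrammarError",
    "module",
    "derive",
    "parse_lstring",
    "format_lstring",
    "check_balance",
]

# One-character turtle symbols allowed alongside alphabetic module names.
_TOKEN_RE = re.compile(r"\s*([A-Za-z_][A-Za-z_0-9]*|[-+&^/\\\[\]])(?:\(([^)]*)\))?")


class GrammarError(ValueError):
    """A production emitted a bracket-unbalanced successor, or a parse failed."""


@dataclass(frozen=True)
class ModuleInstance:
    symbol: str
    params: tuple[float, ...] = ()

    def __post_init__(self):
        if not self.symbol:
            raise GrammarError("module symbol must be non-empty")

    def with_params(self, *params: float) -> "ModuleInstance":
        return ModuleInstance(self.symbol, tuple(float(p) for p in params))


def module(symbol: str, *params: float) -> ModuleInstance:
    return ModuleInstance(symbol, tuple(float(p) for p in params))


LString = list  # list[ModuleInstance]


@dataclass
class Production:
    """Rewrites one module symbol.

    ``successor(params, clock, rng)`` returns the replacement sequence;
    ``condition(params, clock)`` gates applicability (None = always).
    """

    symbol: str
    successor: Callable[[tuple, float, object], Sequence[ModuleInstance]]
    condition: Optional[Callable[[tuple, float], bool]] = None
    name: str = ""

    def matches(self, m: ModuleInstance, clock: float) -> bool:
        if m.symbol != self.symbol:
            return False
        return self.condition is None or bool(self.condition(m.params, clock))


def check_balance(s: Iterable[ModuleInstance], *, allow_open: bool = False) -> int:
    """Return bracket depth delta; raise GrammarError on negative excursion."""
    depth = 0
    for m in s:
        if m.symbol == "[":
            depth += 1
        elif m.symbol == "]":
            depth -= 1
            if depth < 0:
                raise GrammarError("unbalanced brackets: ']' without matching '['")
    if depth != 0 and not allow_open:
        raise GrammarError(f"unbalanced brackets: {depth} unclosed '['")
    return depth


def derive(
    axiom: Sequence[ModuleInstance],
    productions: Sequence[Production],
    dt: float = 0.1,
    n_steps: int = 0,
    rng=None,
    aging: Optional[dict] = None,
) -> list[ModuleInstance]:
    """Apply ``n_steps`` parallel rewriting steps to ``axiom``.

    ``aging`` maps a symbol to the index of its age parameter; unmatched
    modules of those symbols have that parameter advanced by ``dt``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    aging = aging or {}
    string = list(axiom)
    check_balance(string)
    by_symbol: dict[str, list[Production]] = {}
    for p in productions:
        by_symbol.setdefault(p.symbol, []).append(p)

    for step in range(n_steps):
        clock = step * dt
        out: list[ModuleInstance] = []
        for m in string:
            applied = False
            for p in by_symbol.get(m.symbol, ()):
                if p.matches(m, clock):
                    succ = list(p.successor(m.params, clock, rng))
                    try:
                        check_balance(succ)
                    except GrammarError as e:
                        label = p.name or p.symbol
                        raise GrammarError(f"production '{label}': {e}") from e
                    out.extend(succ)
                    applied = True
                    break
            if not applied:
                if m.symbol in aging:
                    idx = aging[m.symbol]
                    params = list(m.params)
                    params[idx] += dt
                    m = ModuleInstance(m.symbol, tuple(params))
                out.append(m)
        string = out
    return string


# -- text serialization ---------------------------------------------------

def _fmt_num(x: float) -> str:
    if float(x).is_integer() and abs(x) < 1e15:
        return str(int(x))
    return repr(float(x))


def format_lstring(s: Sequence[ModuleInstance]) -> str:
    parts = []
    for m in s:
        if m.params:
            parts.append(f"{m.symbol}({','.join(_fmt_num(p) for p in m.params)})")
        else:
            parts.append(m.symbol)
    return "".join(parts)


def parse_lstring(text: str) -> list[ModuleInstance]:
    out: list[ModuleInstance] = []
    pos = 0
    while pos < len(text):
        if text[pos].isspace():
            pos += 1
            continue
        mo = _TOKEN_RE.match(text, pos)
        if not mo:
            raise GrammarError(f"cannot parse L-string at position {pos}: {text[pos:pos+10]!r}")
        sym, argstr = mo.group(1), mo.group(2)
        params: tuple[float, ...] = ()
        if argstr is not None and argstr.strip():
            try:
                params = tuple(float(a) for a in argstr.split(","))
            except ValueError as e:
                raise GrammarError(f"bad parameter list {argstr!r} for {sym}") from e
        out.append(ModuleInstance(sym, params))
        pos = mo.end()
    check_balance(out)
    return out
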