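"""Elementary metabolite unit (EMU) decomposition.

An EMU is a distinct subset of a metabolite's traced atoms; its labeling
state is a mass isotopomer distribution (MID) of length size+1.  Predicting
a measured MID never requires the full isotopomer space (2^n states for an
n-carbon metabolite) — only the EMUs lying on backward atom paths from the
measurement targets.  This module performs that backward trace through the
reaction atom maps and assembles the resulting size-layered EMU reaction
network, whose edges are weighted by fluxes and whose condensation
reactions appear as convolution source terms.

Molecular symmetry (a rotationally symmetric molecule such as succinate)
is handled by orientation averaging: every producing edge into a symmetric
metabolite is split 50/50 between the two equivalent atom orientations,
which is exactly the infinite-rate limit of the "flipping flux" device.
Prochiral metabolites (e.g. citrate) carry no symmetry flag and are left
untouched.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .model import ModelError, NetworkModel

__all__ = ["EMU", "EMUEdge", "EMUNetwork", "decompose", "canonicalize_symmetric"]

_EMU_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*\[\s*([\d,\-\s]+)\s*\]\s*$")


@dataclass(frozen=True, order=True)
class EMU:
    """A metabolite moiety: ``metabolite`` plus sorted 1-based atom indices."""

    metabolite: str
    atoms: tuple[int, ...]

    def __post_init__(self):
        if not self.atoms:
            raise ModelError("EMU needs at least one atom")
        if tuple(sorted(set(self.atoms))) != self.atoms:
            object.__setattr__(self, "atoms", tuple(sorted(set(self.atoms))))

    @property
    def size(self) -> int:
        return len(self.atoms)

    @classmethod
    def parse(cls, label: str) -> "EMU":
        """Parse ``Met[1-3]``, ``Met[1,3]`` or ``Met[2]``."""
        m = _EMU_RE.match(label)
        if not m:
            raise ModelError(f"cannot parse EMU label {label!r}")
        atoms: list[int] = []
        for part in m.group(2).split(","):
            part = part.strip()
            if "-" in part:
                lo, hi = part.split("-")
                atoms.extend(range(int(lo), int(hi) + 1))
            elif part:
                atoms.append(int(part))
        return cls(m.group(1), tuple(sorted(set(atoms))))

    def __str__(self) -> str:
        a = self.atoms
        if len(a) > 1 and a == tuple(range(a[0], a[-1] + 1)):
            return f"{self.metabolite}[{a[0]}-{a[-1]}]"
        return f"{self.metabolite}[{','.join(map(str, a))}]"


@dataclass(frozen=True)
class EMUEdge:
    """A producing edge: ``target`` is made through ``flux_id`` from
    ``sources`` (one EMU, or several combined by MID convolution).
    ``weight`` scales the flux (0.5 per orientation of a symmetric target;
    merged duplicate edges accumulate)."""

    flux_id: str
    sources: tuple[EMU, ...]
    target: EMU
    weight: float = 1.0


@dataclass
class EMUNetwork:
    model: NetworkModel
    edges: list[EMUEdge] = field(default_factory=list)
    source_emus: set[EMU] = field(default_factory=set)
    targets: tuple[EMU, ...] = ()

    @property
    def emus(self) -> list[EMU]:
        seen = set(self.source_emus)
        for e in self.edges:
            seen.add(e.target)
            seen.update(e.sources)
        return sorted(seen)

    def by_size(self) -> dict[int, list[EMU]]:
        out: dict[int, list[EMU]] = {}
        for e in self.emus:
            out.setdefault(e.size, []).append(e)
        return dict(sorted(out.items()))

    def incoming(self, emu: EMU) -> list[EMUEdge]:
        return [e for e in self.edges if e.target == emu]

    def export_edges(self) -> str:
        """Plain-text edge list for debugging and tests."""
        lines = []
        for e in sorted(self.edges, key=lambda e: (e.target, e.flux_id, e.sources)):
            src = " + ".join(str(s) for s in e.sources)
            w = "" if e.weight == 1.0 else f" x{e.weight:g}"
            lines.append(f"{e.target} <- {e.flux_id}{w} : {src}")
        return "\n".join(lines) + "\n"


def canonicalize_symmetric(model: NetworkModel, emu: EMU) -> tuple[EMU, float]:
    """Map an EMU on a symmetric metabolite to its orbit representative.

    Returns ``(representative, weight)`` where the representative is the
    lexicographically smaller of the atom set and its symmetry image, and
    the weight is the per-orientation producing share: 0.5 when the two
    orientations are distinct, 1.0 when the EMU is a fixed point of the
    involution (or the metabolite has no symmetry).
    """
    spec = model.metabolite(emu.metabolite)
    if spec.symmetry is None:
        return emu, 1.0
    image = tuple(sorted(spec.symmetry[a - 1] for a in emu.atoms))
    if image == emu.atoms:
        return emu, 1.0
    rep = min(emu.atoms, image)
    return EMU(emu.metabolite, rep), 0.5


def _orientations(model: NetworkModel, emu: EMU) -> list[tuple[tuple[int, ...], float]]:
    """Atom tuples to trace backward for each producing orientation."""
    spec = model.metabolite(emu.metabolite)
    if spec.symmetry is None:
        return [(emu.atoms, 1.0)]
    image = tuple(sorted(spec.symmetry[a - 1] for a in emu.atoms))
    if image == emu.atoms:
        # self-symmetric: both orientations trace identical atoms
        return [(emu.atoms, 1.0)]
    return [(emu.atoms, 0.5), (image, 0.5)]


def decompose(model: NetworkModel, targets: list[EMU | str]) -> EMUNetwork:
    """Backward-trace the minimal EMU network that predicts ``targets``.

    For every non-source EMU, each reaction producing its metabolite
    contributes one edge whose sources are found by following the atom
    letters back to the substrates; a condensation that draws atoms from
    several substrates yields a convolution source term.  Raises
    :class:`ModelError` when a required EMU has no producer and is not a
    tracer source (a dead end no label can reach).
    """
    target_emus = []
    for t in targets:
        emu = EMU.parse(t) if isinstance(t, str) else t
        spec = model.metabolite(emu.metabolite)
        if any(a < 1 or a > spec.n_atoms for a in emu.atoms):
            raise ModelError(f"EMU {emu} references atoms outside 1..{spec.n_atoms}")
        emu, _ = canonicalize_symmetric(model, emu)
        target_emus.append(emu)

    net = EMUNetwork(model=model, targets=tuple(target_emus))
    edge_index: dict[tuple[str, tuple[EMU, ...], EMU], float] = {}
    visited: set[EMU] = set()
    stack = list(dict.fromkeys(target_emus))
    while stack:
        emu = stack.pop()
        if emu in visited:
            continue
        visited.add(emu)
        spec = model.metabolite(emu.metabolite)
        if spec.role == "source":
            net.source_emus.add(emu)
            continue
        n_edges = 0
        for rxn in model.reactions:
            for met, letters in rxn.products:
                if met != emu.metabolite:
                    continue
                for atoms, weight in _orientations(model, emu):
                    needed = {letters[a - 1] for a in atoms}
                    sources = []
                    for smet, sletters in rxn.substrates:
                        pos = tuple(
                            i + 1 for i, c in enumerate(sletters) if c in needed
                        )
                        if pos:
                            src, _ = canonicalize_symmetric(model, EMU(smet, pos))
                            sources.append(src)
                    if not sources:
                        raise ModelError(
                            f"{rxn.flux_id}: no substrate supplies atoms of {emu}"
                        )
                    key = (rxn.flux_id, tuple(sorted(sources)), emu)
                    edge_index[key] = edge_index.get(key, 0.0) + weight
                    for s in sources:
                        if s not in visited:
                            stack.append(s)
                    n_edges += 1
        if n_edges == 0:
            raise ModelError(
                f"EMU {emu} has no producing reaction and is not a tracer source"
            )
    net.edges = [
        EMUEdge(flux_id=f, sources=srcs, target=tgt, weight=w)
        for (f, srcs, tgt), w in sorted(edge_index.items())
    ]
    return net
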