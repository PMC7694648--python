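"""Steady-state labeling prediction.

Under metabolic and isotopic steady state, the MID of a metabolite is the
flux-weighted average of its substrates' MIDs: for production fluxes f_i
delivering labeling m_i to a product with labeling m,

    sum_i f_i (m_i - m) = 0.

Grouping the unknown EMUs by size, the balances within one size form a
linear system once the (strictly smaller) convolution inputs are known, so
the whole network is solved size by size with dense direct solves.  A
brute-force full-isotopomer solver over the complete 2^n state space is
provided as an independent cross-check for small networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product as iproduct

import numpy as np

from .emu import EMU, EMUNetwork, canonicalize_symmetric, decompose
from .model import FluxState, ModelError, NetworkModel, TracerSpec

__all__ = [
    "MID",
    "convolve",
    "enrichment",
    "tracer_mid",
    "solve_steady",
    "positional_enrichment",
    "brute_force_isotopomer_steady",
]

CLIP_TOL = 1e-12


@dataclass(frozen=True)
class MID:
    """Mass isotopomer distribution: fractions[k] is the M+k abundance."""

    fractions: tuple[float, ...]

    def __post_init__(self):
        arr = np.asarray(self.fractions, dtype=float)
        if arr.min(initial=0.0) < -CLIP_TOL:
            raise ModelError(f"MID has negative fraction {arr.min():g}")
        arr = np.clip(arr, 0.0, None)
        total = arr.sum()
        if not np.isfinite(total) or total <= 0:
            raise ModelError("MID does not sum to a positive value")
        object.__setattr__(self, "fractions", tuple(arr / total))

    @property
    def n_atoms(self) -> int:
        return len(self.fractions) - 1

    def __getitem__(self, k: int) -> float:
        return self.fractions[k]

    def __len__(self) -> int:
        return len(self.fractions)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.fractions)


def convolve(a: MID, b: MID) -> MID:
    """MID of two moieties joined by a condensation reaction.

    The substrates combine independently, so mass shifts add:
    result[k] = sum_j a[j] * b[k-j].
    """
    return MID(tuple(np.convolve(a.as_array(), b.as_array())))


def enrichment(mid: MID) -> float:
    """Average per-atom labeled fraction: sum_k (k/n) * mid[k]."""
    n = mid.n_atoms
    if n == 0:
        return 0.0
    k = np.arange(n + 1)
    return float(np.dot(k / n, mid.as_array()))


def tracer_mid(model: NetworkModel, tracer: TracerSpec, emu: EMU) -> MID:
    """MID of a source-metabolite EMU under the tracer mixture.

    Isotopic purity is taken as 100%: a mixture component with labeled
    position set P puts the whole mole fraction at mass |atoms ∩ P|.
    Source metabolites absent from the tracer are unlabeled.
    """
    spec = model.metabolite(emu.metabolite)
    if spec.role != "source":
        raise ModelError(f"{emu.metabolite} is not a source metabolite")
    out = np.zeros(emu.size + 1)
    entries = tracer.mixtures.get(emu.metabolite)
    if entries is None:
        out[0] = 1.0
    else:
        for positions, frac in entries:
            out[len(positions & set(emu.atoms))] += frac
    return MID(tuple(out))


def _known_source_mid(sources, solved) -> np.ndarray:
    """MID array of an edge source term from already-solved EMUs."""
    arr = solved[sources[0]]
    for s in sources[1:]:
        arr = np.convolve(arr, solved[s])
    return arr


def solve_steady(
    emunet: EMUNetwork, fluxes: FluxState | dict, tracer: TracerSpec
) -> dict[EMU, MID]:
    """Solve the steady-state labeling balances of an EMU network.

    Sizes are processed in ascending order; within one size the unknown
    MIDs satisfy a linear system A X = B where the diagonal holds each
    EMU's total inflow, same-size single-EMU sources couple off-diagonally,
    and tracer sources plus smaller-size convolutions form the right-hand
    side.  Raises :class:`ModelError` for an EMU with zero total inflow
    (the system would be singular).
    """
    model = emunet.model
    solved: dict[EMU, np.ndarray] = {}
    for emu in emunet.source_emus:
        solved[emu] = tracer_mid(model, tracer, emu).as_array()

    incoming: dict[EMU, list] = {}
    for edge in emunet.edges:
        incoming.setdefault(edge.target, []).append(edge)

    for size, emus in emunet.by_size().items():
        unknown = [e for e in emus if e not in solved]
        if not unknown:
            continue
        col = {e: j for j, e in enumerate(unknown)}
        n = len(unknown)
        A = np.zeros((n, n))
        B = np.zeros((n, size + 1))
        for e in unknown:
            i = col[e]
            total_in = 0.0
            for edge in incoming.get(e, []):
                f = float(fluxes[edge.flux_id]) * edge.weight
                total_in += f
                src = edge.sources
                if len(src) == 1 and src[0] in col:
                    A[i, col[src[0]]] -= f
                else:
                    B[i] += f * _known_source_mid(src, solved)
            if total_in <= 0.0:
                in_ids = sorted({edge.flux_id for edge in incoming.get(e, [])})
                raise ModelError(
                    f"EMU {e} has zero total inflow (fluxes {in_ids}); "
                    "labeling system is singular"
                )
            A[i, i] += total_in
        try:
            X = np.linalg.solve(A, B)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"singular labeling system at size {size}: {exc}") from None
        for e, row in zip(unknown, X):
            solved[e] = row
    return {e: MID(tuple(arr)) for e, arr in solved.items()}


def positional_enrichment(
    model: NetworkModel,
    fluxes: FluxState | dict,
    tracer: TracerSpec,
    metabolite: str,
    position: int,
) -> float:
    """Labeled fraction of one atom position (a weight-1 cumomer).

    Equals the M+1 fraction of the size-1 EMU at that position.
    """
    spec = model.metabolite(metabolite)
    if not 1 <= position <= spec.n_atoms:
        raise ModelError(f"{metabolite} position {position} outside 1..{spec.n_atoms}")
    target = EMU(metabolite, (position,))
    net = decompose(model, [target])
    rep, _ = canonicalize_symmetric(model, target)
    mids = solve_steady(net, fluxes, tracer)
    return mids[rep][1]


# ---------------------------------------------------------------------------
# brute-force full-isotopomer oracle


def _isotopomer_sources(model: NetworkModel, tracer: TracerSpec) -> dict[str, np.ndarray]:
    out = {}
    for m in model.metabolites:
        if m.role != "source":
            continue
        dist = np.zeros(2**m.n_atoms)
        entries = tracer.mixtures.get(m.name, ((frozenset(), 1.0),))
        for positions, frac in entries:
            idx = sum(1 << (p - 1) for p in positions)
            dist[idx] += frac
        out[m.name] = dist
    return out


def _product_distribution(model, rxn, met_letters, dists):
    """Isotopomer distribution delivered to one product occurrence."""
    met, letters = met_letters
    n = model.metabolite(met).n_atoms
    subs = rxn.substrates
    out = np.zeros(2**n)
    # letter -> (substrate index, atom position)
    origin = {}
    for si, (smet, sletters) in enumerate(subs):
        for pos, c in enumerate(sletters):
            origin[c] = (si, pos)
    sub_states = [np.nonzero(dists[smet] > 0)[0] for smet, _ in subs]
    sub_probs = [dists[smet] for smet, _ in subs]
    for combo in iproduct(*sub_states):
        p = 1.0
        for si, state in enumerate(combo):
            p *= sub_probs[si][state]
        if p == 0.0:
            continue
        label = 0
        for k, c in enumerate(letters):
            si, pos = origin[c]
            if combo[si] >> pos & 1:
                label |= 1 << k
        out[label] += p
    spec = model.metabolite(met)
    if spec.symmetry is not None:
        flipped = np.zeros_like(out)
        for state in np.nonzero(out)[0]:
            img = 0
            for k in range(n):
                if state >> k & 1:
                    img |= 1 << (spec.symmetry[k] - 1)
            flipped[img] += out[state]
        out = 0.5 * (out + flipped)
    return out


def brute_force_isotopomer_steady(
    model: NetworkModel,
    fluxes: FluxState | dict,
    tracer: TracerSpec,
    max_atoms: int = 8,
    tol: float = 1e-13,
    max_iter: int = 200_000,
) -> dict[str, np.ndarray]:
    """Steady state of the full isotopomer master equations (test oracle).

    Tracks the complete 2^n isotopomer distribution of every non-source
    metabolite under uniform unit pools and relaxes the master equations
    d x / dt = (sum_i f_i p_i(x)) - (sum_i f_i) x to their fixed point by
    damped iteration.  Exponential in atom count: refuse metabolites with
    more than ``max_atoms`` traced atoms.
    """
    for m in model.metabolites:
        if m.role != "source" and m.n_atoms > max_atoms:
            raise ModelError(
                f"{m.name} has {m.n_atoms} atoms; brute-force cap is {max_atoms}"
            )
    dists = _isotopomer_sources(model, tracer)
    tracked = [m for m in model.metabolites if m.role != "source"]
    for m in tracked:
        init = np.zeros(2**m.n_atoms)
        init[0] = 1.0
        dists[m.name] = init

    producers: dict[str, list] = {m.name: [] for m in tracked}
    for rxn in model.reactions:
        for met, letters in rxn.products:
            if met in producers:
                producers[met].append((rxn, (met, letters)))

    for _ in range(max_iter):
        delta = 0.0
        new = {}
        for m in tracked:
            total = 0.0
            acc = np.zeros(2**m.n_atoms)
            for rxn, met_letters in producers[m.name]:
                f = float(fluxes[rxn.flux_id])
                if f == 0.0:
                    continue
                total += f
                acc += f * _product_distribution(model, rxn, met_letters, dists)
            if total <= 0.0:
                raise ModelError(f"{m.name} has zero total production flux")
            new[m.name] = acc / total
            delta = max(delta, float(np.abs(new[m.name] - dists[m.name]).max()))
        dists.update(new)
        if delta < tol:
            break
    else:
        raise ModelError("brute-force isotopomer iteration did not converge")
    return dists


def isotopomer_mid(dist: np.ndarray) -> MID:
    """Marginalize a full isotopomer distribution to its MID."""
    n = int(np.log2(len(dist)))
    out = np.zeros(n + 1)
    for state, p in enumerate(dist):
        out[int(state).bit_count()] += p
    return MID(tuple(out))
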