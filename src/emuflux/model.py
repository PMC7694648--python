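"""Atom-transition network models, tracers, fluxes, and measurements.

A network is a set of metabolites carrying traced atoms (carbons, in the
usual 13C experiment) and a set of irreversible reaction steps whose atom
maps are written with letter strings: ``f2: FBP (abcdef) -> DHAP (abc) + GAP (def)``
states that FBP carbons 1-3 become DHAP carbons 1-3 and FBP carbons 4-6
become GAP carbons 1-3.  A reversible reaction is written as two steps with
separate flux identifiers, so every flux is nonnegative.

Steady-state mass balance requires, for every *balanced* metabolite, that
the production fluxes sum to the consumption fluxes.  These homogeneous
linear constraints (plus any externally fixed fluxes, e.g. a measured
uptake rate) leave a small number of *free fluxes*; the full flux vector is
an affine function of the free ones, computed here by Gaussian elimination
with lexicographic pivoting so the choice of free fluxes is deterministic.
"""

from __future__ import annotations

import csv
import io
import math
import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MetaboliteSpec",
    "ReactionStep",
    "NetworkModel",
    "TracerSpec",
    "FluxState",
    "FreeFluxSpec",
    "Measurement",
    "MeasurementSet",
    "ModelError",
    "ParseError",
    "parse_model",
    "write_model",
    "balance_constraints",
    "derive_free_fluxes",
    "read_measurements",
    "write_measurements",
    "parse_tracer",
]

BALANCE_RTOL = 1e-9

ROLES = ("balanced", "source", "sink")


class ModelError(ValueError):
    """Invalid network model, tracer, flux state, or measurement set."""


class ParseError(ModelError):
    """Parse failure carrying the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class MetaboliteSpec:
    """A metabolite with ``n_atoms`` traced atoms.

    ``role`` is ``balanced`` (mass balance applies), ``source`` (labeling
    fixed by the tracer, no balance) or ``sink`` (absorbing, no balance).
    ``symmetry``, when present, is an involution on atom indices 1..n
    expressing rotational molecular symmetry (e.g. succinate's 4321).
    ``pool_size`` is the metabolite amount c*V in nmol, used only by
    non-stationary simulations.
    """

    name: str
    n_atoms: int
    role: str = "balanced"
    symmetry: tuple[int, ...] | None = None
    pool_size: float | None = None

    def __post_init__(self):
        if self.n_atoms < 1:
            raise ModelError(f"{self.name}: n_atoms must be >= 1")
        if self.role not in ROLES:
            raise ModelError(f"{self.name}: unknown role {self.role!r}")
        if self.symmetry is not None:
            perm = self.symmetry
            if sorted(perm) != list(range(1, self.n_atoms + 1)):
                raise ModelError(f"{self.name}: symmetry is not a permutation of 1..{self.n_atoms}")
            if any(perm[perm[i] - 1] != i + 1 for i in range(self.n_atoms)):
                raise ModelError(f"{self.name}: symmetry is not an involution")
        if self.pool_size is not None and not self.pool_size > 0:
            raise ModelError(f"{self.name}: pool_size must be positive")


@dataclass(frozen=True)
class ReactionStep:
    """One irreversible atom-mapped reaction step.

    Each participant is a ``(metabolite, letters)`` pair; letter *k* of the
    string names traced atom position *k* (1-based).  Product letters must
    each come from exactly one substrate letter; substrate letters may be
    dropped (atoms leaving through a sink).
    """

    flux_id: str
    substrates: tuple[tuple[str, str], ...]
    products: tuple[tuple[str, str], ...]


@dataclass(frozen=True)
class NetworkModel:
    name: str
    metabolites: tuple[MetaboliteSpec, ...]
    reactions: tuple[ReactionStep, ...]
    _by_name: dict = field(init=False, repr=False, compare=False, hash=False)

    def __post_init__(self):
        object.__setattr__(self, "_by_name", {m.name: m for m in self.metabolites})
        self._validate()

    def metabolite(self, name: str) -> MetaboliteSpec:
        try:
            return self._by_name[name]
        except KeyError:
            raise ModelError(f"unknown metabolite {name!r}") from None

    @property
    def flux_ids(self) -> tuple[str, ...]:
        return tuple(r.flux_id for r in self.reactions)

    def _validate(self):
        if len(self._by_name) != len(self.metabolites):
            raise ModelError("duplicate metabolite name")
        if not self.reactions:
            raise ModelError("no reactions")
        seen: set[str] = set()
        for r in self.reactions:
            if r.flux_id in seen:
                raise ModelError(f"duplicate flux_id {r.flux_id!r}")
            seen.add(r.flux_id)
            sub_letters: list[str] = []
            for met, letters in r.substrates + r.products:
                spec = self.metabolite(met)
                if len(letters) != spec.n_atoms:
                    raise ModelError(
                        f"{r.flux_id}: atom string {letters!r} for {met} has "
                        f"{len(letters)} letters, expected {spec.n_atoms}"
                    )
            for _, letters in r.substrates:
                sub_letters.extend(letters)
            if len(set(sub_letters)) != len(sub_letters):
                raise ModelError(f"{r.flux_id}: repeated substrate atom letter")
            sub_set = set(sub_letters)
            prod_letters: list[str] = []
            for _, letters in r.products:
                prod_letters.extend(letters)
            if len(set(prod_letters)) != len(prod_letters):
                raise ModelError(f"{r.flux_id}: repeated product atom letter")
            missing = set(prod_letters) - sub_set
            if missing:
                raise ModelError(
                    f"{r.flux_id}: product letter(s) {''.join(sorted(missing))!r} "
                    "not present on the substrate side"
                )
        produced = {m: 0 for m in self._by_name}
        consumed = {m: 0 for m in self._by_name}
        for r in self.reactions:
            for met, _ in r.products:
                produced[met] += 1
            for met, _ in r.substrates:
                consumed[met] += 1
        for m in self.metabolites:
            if m.role == "balanced":
                if produced[m.name] == 0:
                    raise ModelError(f"balanced metabolite {m.name} has no producing step")
                if consumed[m.name] == 0:
                    raise ModelError(f"balanced metabolite {m.name} has no consuming step")


@dataclass(frozen=True)
class TracerSpec:
    """Isotopic composition of each source metabolite.

    ``mixtures`` maps a source metabolite to a list of
    ``(labeled positions, mole fraction)`` entries; positions are 1-based
    atom indices carrying the heavy isotope (purity is taken as 100%).
    Source metabolites absent from the mapping are unlabeled.
    """

    mixtures: dict[str, tuple[tuple[frozenset[int], float], ...]]

    def __post_init__(self):
        for met, entries in self.mixtures.items():
            total = sum(frac for _, frac in entries)
            if any(frac < 0 or frac > 1 for _, frac in entries):
                raise ModelError(f"tracer {met}: mole fractions must lie in [0, 1]")
            if abs(total - 1.0) > 1e-9:
                raise ModelError(f"tracer {met}: mole fractions sum to {total}, expected 1")

    @classmethod
    def single(cls, metabolite: str, positions: set[int] | frozenset[int]) -> "TracerSpec":
        return cls({metabolite: ((frozenset(positions), 1.0),)})

    @classmethod
    def from_dict(cls, raw: dict) -> "TracerSpec":
        mixtures = {}
        for met, entries in raw.items():
            mixtures[met] = tuple(
                (frozenset(e["positions"]), float(e["fraction"])) for e in entries
            )
        return cls(mixtures)


class FluxState(dict):
    """Mapping flux_id -> nonnegative rate (e.g. nmol/h)."""

    def __init__(self, values: dict[str, float]):
        for k, v in values.items():
            if v < 0:
                raise ModelError(f"flux {k} is negative ({v})")
        super().__init__(values)

    def check_balance(self, model: NetworkModel, rtol: float = BALANCE_RTOL):
        """Raise unless every balanced metabolite satisfies Sum(prod) = Sum(cons)."""
        for name, eq in balance_constraints(model).items():
            net = sum(c * self[f] for f, c in eq.items())
            scale = max((abs(self[f]) for f in eq), default=1.0)
            if abs(net) > rtol * max(scale, 1.0):
                raise ModelError(f"flux state violates balance of {name} (net {net:g})")


@dataclass(frozen=True)
class FreeFluxSpec:
    """Affine parameterization full_fluxes = offset + basis @ free_values.

    ``free_ids`` are the free flux coordinates (non-pivot columns of the
    balance system under lexicographic Gaussian elimination, so the choice
    is deterministic); ``fixed`` holds externally assigned fluxes.  The map
    satisfies every balance constraint identically.
    """

    model: NetworkModel
    free_ids: tuple[str, ...]
    fixed: dict[str, float]
    offset: np.ndarray
    basis: np.ndarray  # shape (n_fluxes, n_free)
    bounds: tuple[tuple[float, float], ...]  # per free flux

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.model.flux_ids

    def flux_state(self, free_values) -> FluxState:
        full = self.full_vector(free_values)
        return FluxState({k: float(v) for k, v in zip(self.all_ids, full)})

    def full_vector(self, free_values) -> np.ndarray:
        """Full flux vector; may be negative for infeasible free values."""
        u = np.asarray(free_values, dtype=float)
        if u.shape != (len(self.free_ids),):
            raise ModelError(
                f"expected {len(self.free_ids)} free values, got shape {u.shape}"
            )
        return self.offset + self.basis @ u


_MET_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*,\s*(\d+)\s*,\s*(\w+)\s*(.*)$")
_RXN_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*:\s*(.+?)\s*->\s*(.+?)\s*$")
_TERM_RE = re.compile(r"^\s*([A-Za-z_]\w*)\s*\(\s*([A-Za-z]*)\s*\)\s*$")


def _parse_side(text: str, line: int) -> tuple[tuple[str, str], ...]:
    terms = []
    for part in text.split("+"):
        m = _TERM_RE.match(part)
        if not m:
            raise ParseError(f"cannot parse reaction term {part.strip()!r}", line)
        terms.append((m.group(1), m.group(2)))
    return tuple(terms)


def parse_model(text: str, name: str = "model") -> NetworkModel:
    """Parse the plain-text model dialect.

    Metabolite lines: ``name, n_atoms, role[, pool=<nmol>][, symmetry=<perm>]``.
    Reaction lines: ``flux_id: M1 (abc) + M2 (de) -> M3 (abcde)``.
    ``#`` starts a comment.  Errors carry the offending line number.
    """
    metabolites: list[MetaboliteSpec] = []
    raw_reactions: list[tuple[int, str, str, str]] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        rxn = _RXN_RE.match(line)
        if rxn and "->" in line:
            raw_reactions.append((lineno, rxn.group(1), rxn.group(2), rxn.group(3)))
            continue
        met = _MET_RE.match(line)
        if not met:
            raise ParseError(f"cannot parse line {line!r}", lineno)
        mname, n_atoms, role, rest = met.groups()
        symmetry = None
        pool = None
        for opt in filter(None, (p.strip() for p in rest.split(","))):
            if opt.startswith("pool="):
                pool = float(opt[5:])
            elif opt.startswith("symmetry="):
                symmetry = tuple(int(c) for c in opt[9:].strip())
            else:
                raise ParseError(f"unknown metabolite option {opt!r}", lineno)
        try:
            metabolites.append(
                MetaboliteSpec(mname, int(n_atoms), role, symmetry=symmetry, pool_size=pool)
            )
        except ModelError as exc:
            raise ParseError(str(exc), lineno) from None

    reactions = []
    for lineno, flux_id, lhs, rhs in raw_reactions:
        reactions.append(
            ReactionStep(flux_id, _parse_side(lhs, lineno), _parse_side(rhs, lineno))
        )
    if not reactions:
        raise ParseError("no reactions")
    try:
        return NetworkModel(name, tuple(metabolites), tuple(reactions))
    except ModelError as exc:
        raise ParseError(str(exc)) from None


def write_model(model: NetworkModel) -> str:
    """Serialize back to the model dialect (inverse of :func:`parse_model`)."""
    out = [f"# {model.name}"]
    for m in model.metabolites:
        line = f"{m.name}, {m.n_atoms}, {m.role}"
        if m.pool_size is not None:
            line += f", pool={m.pool_size:g}"
        if m.symmetry is not None:
            line += ", symmetry=" + "".join(str(i) for i in m.symmetry)
        out.append(line)
    for r in model.reactions:
        lhs = " + ".join(f"{met} ({letters})" for met, letters in r.substrates)
        rhs = " + ".join(f"{met} ({letters})" for met, letters in r.products)
        out.append(f"{r.flux_id}: {lhs} -> {rhs}")
    return "\n".join(out) + "\n"


def balance_constraints(model: NetworkModel) -> dict[str, dict[str, float]]:
    """Per-balanced-metabolite homogeneous balance equations.

    Returns ``{metabolite: {flux_id: coefficient}}`` where production
    contributes +1 per occurrence and consumption -1; each equation reads
    Sum(coeff * flux) = 0.
    """
    eqs: dict[str, dict[str, float]] = {}
    balanced = {m.name for m in model.metabolites if m.role == "balanced"}
    for r in model.reactions:
        for met, _ in r.products:
            if met in balanced:
                eqs.setdefault(met, {})
                eqs[met][r.flux_id] = eqs[met].get(r.flux_id, 0.0) + 1.0
        for met, _ in r.substrates:
            if met in balanced:
                eqs.setdefault(met, {})
                eqs[met][r.flux_id] = eqs[met].get(r.flux_id, 0.0) - 1.0
    # drop cancelled coefficients
    return {
        met: {f: c for f, c in eq.items() if c != 0.0}
        for met, eq in eqs.items()
        if any(c != 0.0 for c in eq.values())
    }


def _constraint_matrix(model: NetworkModel, fixed: dict[str, float]):
    ids = list(model.flux_ids)
    idx = {f: j for j, f in enumerate(ids)}
    eqs = balance_constraints(model)
    rows = []
    rhs = []
    for met in sorted(eqs):
        row = np.zeros(len(ids))
        for f, c in eqs[met].items():
            row[idx[f]] = c
        rows.append(row)
        rhs.append(0.0)
    for f in sorted(fixed):
        if f not in idx:
            raise ModelError(f"fixed flux {f!r} is not in the model")
        row = np.zeros(len(ids))
        row[idx[f]] = 1.0
        rows.append(row)
        rhs.append(float(fixed[f]))
    A = np.array(rows) if rows else np.zeros((0, len(ids)))
    b = np.array(rhs)
    return ids, A, b


def derive_free_fluxes(
    model: NetworkModel,
    fixed: dict[str, float] | None = None,
    bounds: tuple[float, float] = (0.0, 1e4),
) -> FreeFluxSpec:
    """Free-flux parameterization of the balance + fixed-flux system.

    Gaussian elimination over the constraint matrix with columns taken in
    the model's flux order selects pivot (dependent) columns greedily; the
    remaining columns are the free fluxes.  On the canonical upper-glycolysis
    network with the uptake flux fixed this yields the aldolase and TPI
    reverse fluxes as the two free coordinates.

    Raises :class:`ModelError` if the fixed assignments are inconsistent
    with the balance constraints.
    """
    fixed = dict(fixed or {})
    ids, A, b = _constraint_matrix(model, fixed)
    n = len(ids)
    tol = 1e-10 * max(1.0, float(np.abs(A).max(initial=0.0)))

    # greedy lexicographic pivoting: dependent columns are those that raise rank
    dependent: list[int] = []
    rank = int(np.linalg.matrix_rank(A, tol=tol)) if A.size else 0
    cur = np.zeros((A.shape[0], 0))
    for j in range(n):
        cand = np.column_stack([cur, A[:, j]])
        if np.linalg.matrix_rank(cand, tol=tol) > cur.shape[1]:
            cur = cand
            dependent.append(j)
            if len(dependent) == rank:
                break
    free_idx = [j for j in range(n) if j not in set(dependent)]

    Ad = A[:, dependent]
    # offset: solve with free values = 0
    off_d, res, rk, _ = np.linalg.lstsq(Ad, b, rcond=None)
    if rk < len(dependent):
        raise ModelError("degenerate constraint system")
    if not np.allclose(Ad @ off_d, b, atol=1e-7 * max(1.0, np.abs(b).max(initial=1.0))):
        raise ModelError("fixed fluxes are inconsistent with the balance constraints")
    basis = np.zeros((n, len(free_idx)))
    offset = np.zeros(n)
    for row, j in enumerate(dependent):
        offset[j] = off_d[row]
    for col, j in enumerate(free_idx):
        basis[j, col] = 1.0
        dep_col, _, _, _ = np.linalg.lstsq(Ad, -A[:, j], rcond=None)
        resid = Ad @ dep_col + A[:, j]
        if not np.allclose(resid, 0.0, atol=1e-7):
            raise ModelError("fixed fluxes are inconsistent with the balance constraints")
        for row, jj in enumerate(dependent):
            basis[jj, col] = dep_col[row]
    free_ids = tuple(ids[j] for j in free_idx)
    return FreeFluxSpec(
        model=model,
        free_ids=free_ids,
        fixed=fixed,
        offset=offset,
        basis=basis,
        bounds=tuple(bounds for _ in free_ids),
    )


@dataclass(frozen=True)
class Measurement:
    """One observed EMU MID, optionally time-stamped (non-stationary data)."""

    emu: str  # canonical EMU label, e.g. "FBP[1-6]"
    mids: tuple[tuple[int, float], ...]  # (mass shift, fraction), ascending
    sds: tuple[float, ...]
    time: float | None = None


class MeasurementSet(list):
    """List of :class:`Measurement` with validated, renormalized MIDs."""

    @classmethod
    def from_rows(cls, rows) -> "MeasurementSet":
        """Build from (emu, mass_shift, fraction, sd, time) tuples."""
        grouped: dict[tuple[str, float | None], list[tuple[int, float, float]]] = {}
        seen: set[tuple[str, int, float | None]] = set()
        for emu, mass, frac, sd, time in rows:
            key = (emu, int(mass), time)
            if key in seen:
                raise ModelError(f"duplicate measurement for {emu} M+{mass} at time {time}")
            seen.add(key)
            if not sd > 0:
                raise ModelError(f"{emu} M+{mass}: sd must be positive, got {sd}")
            grouped.setdefault((emu, time), []).append((int(mass), float(frac), float(sd)))
        out = cls()
        for (emu, time), entries in grouped.items():
            entries.sort()
            total = sum(f for _, f, _ in entries)
            if not (0.98 <= total <= 1.02):
                raise ModelError(f"{emu}: MID sums to {total:.4f}, outside [0.98, 1.02]")
            out.append(
                Measurement(
                    emu=emu,
                    mids=tuple((m, f / total) for m, f, _ in entries),
                    sds=tuple(s for _, _, s in entries),
                    time=time,
                )
            )
        return out


def read_measurements(text: str) -> MeasurementSet:
    """Read the measurements CSV (columns emu, mass_shift, fraction, sd[, time])."""
    reader = csv.DictReader(io.StringIO(text))
    required = {"emu", "mass_shift", "fraction", "sd"}
    if reader.fieldnames is None or not required <= set(reader.fieldnames):
        raise ModelError(f"measurements CSV must have columns {sorted(required)}")
    rows = []
    for i, row in enumerate(reader, start=2):
        try:
            time_raw = (row.get("time") or "").strip()
            rows.append(
                (
                    row["emu"].strip(),
                    int(row["mass_shift"]),
                    float(row["fraction"]),
                    float(row["sd"]),
                    float(time_raw) if time_raw else None,
                )
            )
        except (TypeError, ValueError) as exc:
            raise ParseError(f"bad measurement row: {exc}", i) from None
    return MeasurementSet.from_rows(rows)


def write_measurements(measurements: MeasurementSet) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf)
    writer.writerow(["emu", "mass_shift", "fraction", "sd", "time"])
    for m in measurements:
        for (mass, frac), sd in zip(m.mids, m.sds):
            writer.writerow(
                [m.emu, mass, f"{frac:.10g}", f"{sd:.10g}", "" if m.time is None else f"{m.time:g}"]
            )
    return buf.getvalue()


def parse_tracer(raw: dict) -> TracerSpec:
    """Build a TracerSpec from a plain mapping (e.g. parsed YAML/JSON)."""
    return TracerSpec.from_dict(raw)
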