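"""Mass-action reaction specifications and a vectorised evaluation engine.

A :class:`ReactionSpec` is pure data; :class:`ReactionNetwork` compiles a list
of specs into index arrays so that all reaction rates for all compartments are
evaluated with a handful of numpy operations per right-hand-side call.
Custom rate laws (SERCA, IP3R, SOCE, PIP2 hydrolysis, diffusion) are *not*
handled here -- they are registered as flux callables on the assembled model.

:func:`mass_action_oracle` is an intentionally naive, dictionary-based
reference implementation used to validate the vectorised path in tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MAX_ORDER = 4  # maximum number of molecule slots per reaction side


@dataclass
class ReactionSpec:
    """One (possibly reversible) mass-action reaction.

    ``reactants``/``products`` are lists of ``(species, stoichiometry)``.
    Rate convention for a species with stoichiometry ``n``: it contributes
    ``conc**n`` to the rate and is consumed/produced at ``n * rate``.
    """

    name: str
    reactants: list[tuple[str, int]]
    products: list[tuple[str, int]]
    kf: float
    kb: float = 0.0
    region: str = "cytosol"      # cytosol | er | membrane
    rate_law: str = "mass_action"

    def __post_init__(self) -> None:
        for side in (self.reactants, self.products):
            for sp, n in side:
                if not isinstance(n, int) or n <= 0:
                    raise ValueError(
                        f"reaction {self.name!r}: stoichiometry of {sp!r} "
                        "must be a positive integer")
        if self.kf < 0 or self.kb < 0:
            raise ValueError(f"reaction {self.name!r}: rates must be >= 0")

    @property
    def reversible(self) -> bool:
        return self.kb > 0

    def species(self) -> set[str]:
        return {sp for sp, _ in self.reactants} | {sp for sp, _ in self.products}


def _expand(side: list[tuple[str, int]]) -> list[str]:
    """[(A,2),(B,1)] -> [A, A, B]"""
    out: list[str] = []
    for sp, n in side:
        out.extend([sp] * n)
    return out


class ReactionNetwork:
    """Compiled mass-action network over a fixed species ordering.

    Parameters
    ----------
    reactions : list of ReactionSpec
    species_index : mapping species name -> row in the concentration matrix
    clamped : names of species whose concentration is supplied externally per
        call (e.g. bath-applied ACh); they appear in rates but receive no
        derivative.
    """

    def __init__(self, reactions: list[ReactionSpec],
                 species_index: dict[str, int],
                 clamped: set[str] | None = None):
        self.reactions = list(reactions)
        self.species_index = dict(species_index)
        self.clamped = set(clamped or ())
        n_sp = len(species_index)

        undeclared = set()
        for rxn in self.reactions:
            if rxn.rate_law != "mass_action":
                raise ValueError(
                    f"reaction {rxn.name!r}: custom rate law {rxn.rate_law!r} "
                    "must be registered as a flux, not a mass-action reaction")
            undeclared |= rxn.species() - set(species_index) - self.clamped
        if undeclared:
            raise KeyError(f"undeclared species: {sorted(undeclared)}")

        # Split every reversible reaction into forward/backward elementary
        # steps; each step has <= MAX_ORDER reactant slots (padded with a
        # virtual 'ones' row at index n_sp).
        ones_row = n_sp + len(self.clamped)
        clamped_rows = {sp: n_sp + i for i, sp in enumerate(sorted(self.clamped))}
        self._clamped_order = sorted(self.clamped)

        steps: list[tuple[float, list[str], list[tuple[str, int]], list[tuple[str, int]]]] = []
        for rxn in self.reactions:
            steps.append((rxn.kf, _expand(rxn.reactants), rxn.reactants, rxn.products))
            if rxn.reversible:
                steps.append((rxn.kb, _expand(rxn.products), rxn.products, rxn.reactants))

        n_steps = len(steps)
        self.n_steps = n_steps
        self.k = np.array([s[0] for s in steps])
        self.slots = np.full((MAX_ORDER, n_steps), ones_row, dtype=np.intp)
        rows: list[int] = []
        cols: list[int] = []
        vals: list[float] = []
        for j, (k, order_list, consumed, produced) in enumerate(steps):
            if len(order_list) > MAX_ORDER:
                raise ValueError("reaction order above supported maximum")
            for slot, sp in enumerate(order_list):
                self.slots[slot, j] = clamped_rows.get(sp, self.species_index.get(sp, ones_row))
            for sp, n in consumed:
                if sp in self.clamped:
                    continue
                rows.append(self.species_index[sp]); cols.append(j); vals.append(-float(n))
            for sp, n in produced:
                if sp in self.clamped:
                    continue
                rows.append(self.species_index[sp]); cols.append(j); vals.append(float(n))
        # dense stoichiometry matrix (n_species x n_steps); both dims are small
        self.stoich = np.zeros((n_sp, n_steps))
        for r, c, v in zip(rows, cols, vals):
            self.stoich[r, c] += v
        self._n_species = n_sp

    def rates(self, conc: np.ndarray, clamped_values: dict[str, float | np.ndarray] | None = None) -> np.ndarray:
        """Per-step rates; ``conc`` has shape (n_species, n_comp)."""
        n_comp = conc.shape[1]
        ext = np.empty((len(self._clamped_order) + 1, n_comp))
        for i, sp in enumerate(self._clamped_order):
            ext[i] = (clamped_values or {}).get(sp, 0.0)
        ext[-1] = 1.0
        full = np.vstack([conc, ext]) if ext.size else conc
        prod = full[self.slots[0]]
        for slot in range(1, MAX_ORDER):
            prod = prod * full[self.slots[slot]]
        return self.k[:, None] * prod

    def derivatives(self, conc: np.ndarray,
                    clamped_values: dict[str, float | np.ndarray] | None = None,
                    out: np.ndarray | None = None) -> np.ndarray:
        """d(conc)/dt with shape (n_species, n_comp)."""
        r = self.rates(conc, clamped_values)
        d = self.stoich @ r
        if out is not None:
            out += d
            return out
        return d

    def dependency_pairs(self) -> set[tuple[str, str]]:
        """(affected, depends_on) species pairs, for Jacobian sparsity."""
        pairs: set[tuple[str, str]] = set()
        for rxn in self.reactions:
            involved = [sp for sp in rxn.species() if sp not in self.clamped]
            fwd_inputs = [sp for sp, _ in rxn.reactants if sp not in self.clamped]
            inputs = list(fwd_inputs)
            if rxn.reversible:
                inputs += [sp for sp, _ in rxn.products if sp not in self.clamped]
            for a in involved:
                for b in inputs:
                    pairs.add((a, b))
        return pairs


def mass_action_oracle(reactions: list[ReactionSpec],
                       concentrations: dict[str, float]) -> dict[str, float]:
    """Naive term-by-term mass-action derivatives (test oracle).

    Walks every reaction and accumulates each species' derivative with plain
    Python arithmetic, independently of the vectorised engine.  Refuses
    custom rate laws.
    """
    for rxn in reactions:
        if rxn.rate_law != "mass_action":
            raise ValueError(f"oracle only handles mass action, got {rxn.rate_law!r}")

    deriv = {sp: 0.0 for sp in concentrations}
    for rxn in reactions:
        for sp in rxn.species():
            if sp not in concentrations:
                raise KeyError(f"missing concentration for {sp!r}")
        fwd = rxn.kf
        for sp, n in rxn.reactants:
            fwd *= concentrations[sp] ** n
        bwd = 0.0
        if rxn.reversible:
            bwd = rxn.kb
            for sp, n in rxn.products:
                bwd *= concentrations[sp] ** n
        net = fwd - bwd
        for sp, n in rxn.reactants:
            deriv[sp] -= n * net
        for sp, n in rxn.products:
            deriv[sp] += n * net
    return deriv
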