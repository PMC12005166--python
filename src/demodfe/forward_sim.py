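"""Discrete-generation Wright–Fisher simulator with selection and linkage.

The engine evolves diploid populations over a linear chromosome whose exonic
bases draw selection coefficients from a discrete-class DFE (introns and
intergenic bases are neutral), under the 5-population demographic model, with
a 10N-generation burn-in followed by a divergence window reaching back to the
human–chimpanzee split during which post-burn-in fixations are logged.
Recurrent beneficial classes and conditioned single sweeps (restart until the
beneficial allele fixes in the required populations) are built on top.

Empirical-scale population sizes are far beyond desk scale, so runs are
expected to use a rescaled model (N/kappa, t/kappa, rates and selection
coefficients x kappa) via :meth:`OOADemography.scaled`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import OOADemography, validate_model
from .sumstats import HaplotypeSample

INTERGENIC, INTRON, EXON = 0, 1, 2
_ELEMENT_NAMES = {INTERGENIC: "intergenic", INTRON: "intron", EXON: "exon"}

DFE_BOUNDARIES = (0.0, 1.0, 10.0, 100.0)  # 2*N_ref*s class edges; f3 open above


@dataclass
class DFEModel:
    """Discrete fitness-effect classes on the 2·N_ref·s scale.

    Deleterious classes f0..f3 sit on boundaries [0,1), [1,10), [10,100),
    [100, 2·N_ref] (s capped at 1, lethal); an optional beneficial class of
    frequency f_b spans ``beneficial_range`` on the same scale.  s is the
    homozygote fitness change; 2·N_ref·s values are uniform within a class.
    """

    n_ref: int
    f: tuple[float, float, float, float] = (0.25, 0.49, 0.04, 0.22)
    h: float = 0.5
    f_b: float = 0.0
    beneficial_range: tuple[float, float] = (1.0, 10.0)

    def __post_init__(self):
        freqs = np.array(self.f, dtype=float)
        if np.any(freqs < 0) or self.f_b < 0:
            raise ValueError("class frequencies must be >= 0")
        if not np.isclose(freqs.sum() + self.f_b, 1.0):
            raise ValueError("class frequencies (+ beneficial) must sum to 1")
        if not self.beneficial_range[0] < self.beneficial_range[1]:
            raise ValueError("beneficial range boundaries must increase")

    def with_beneficial(self, f_b: float, beneficial_range: tuple[float, float]) -> "DFEModel":
        """Rebalance: the beneficial class is taken out of f0."""
        if self.f[0] < f_b:
            raise ValueError(f"f0={self.f[0]} is below the beneficial rate {f_b}")
        f = (self.f[0] - f_b, *self.f[1:])
        return DFEModel(self.n_ref, f, self.h, f_b, beneficial_range)

    def class_bounds(self) -> list[tuple[float, float]]:
        upper = 2.0 * self.n_ref  # s <= 1
        b = DFE_BOUNDARIES
        return [(b[0], b[1]), (b[1], b[2]), (b[2], b[3]), (b[3], max(upper, b[3] + 1.0))]


def draw_fitness_effect(dfe: DFEModel, rng: np.random.Generator) -> tuple[float, str]:
    """Draw (s, class label); deleterious s < 0, beneficial s > 0."""
    probs = list(dfe.f) + [dfe.f_b]
    k = rng.choice(5, p=np.array(probs) / np.sum(probs))
    if k == 4:
        lo, hi = dfe.beneficial_range
        s = rng.uniform(lo, hi) / (2.0 * dfe.n_ref)
        return float(min(s, 1.0)), "beneficial"
    lo, hi = dfe.class_bounds()[k]
    s = rng.uniform(lo, hi) / (2.0 * dfe.n_ref)
    return float(-min(s, 1.0)), f"f{k}"


@dataclass
class ChromosomeLayout:
    """Ordered (kind, length) elements; selection applies to exonic bases."""

    elements: list[tuple[str, int]]

    def __post_init__(self):
        if any(length <= 0 for _, length in self.elements):
            raise ValueError("element lengths must be positive")
        kinds = {k for k, _ in self.elements}
        if not kinds <= set(_ELEMENT_NAMES.values()):
            raise ValueError(f"unknown element kinds: {kinds - set(_ELEMENT_NAMES.values())}")

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.elements)

    def intervals(self, kind: str) -> np.ndarray:
        """0-based half-open intervals of the given element kind."""
        out, pos = [], 0
        for k, length in self.elements:
            if k == kind:
                out.append((pos, pos + length))
            pos += length
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)

    def element_at(self, positions: np.ndarray) -> np.ndarray:
        """Element code per position."""
        bounds, codes, pos = [0], [], 0
        for k, length in self.elements:
            pos += length
            bounds.append(pos)
            codes.append({v: c for c, v in _ELEMENT_NAMES.items()}[k])
        idx = np.clip(np.searchsorted(bounds, positions, side="right") - 1, 0, len(codes) - 1)
        return np.asarray(codes)[idx]

    def exonic_bp(self) -> int:
        iv = self.intervals("exon")
        return int((iv[:, 1] - iv[:, 0]).sum()) if iv.size else 0


def assemble_sweep_chromosome(
    n_functional: int = 7,
    exons_per_region: int = 9,
    exon_length: int = 1317,
    introns_per_region: int = 8,
    intron_length: int = 1520,
    intergenic_length: int = 4322,
) -> ChromosomeLayout:
    """The sweep-scan chromosome: functional regions of alternating exons and
    introns separated by intergenic spacers (defaults give 198,345 bp)."""
    if min(n_functional, exons_per_region, exon_length, intron_length, intergenic_length) <= 0:
        raise ValueError("counts and lengths must be positive")
    elements: list[tuple[str, int]] = []
    for _ in range(n_functional):
        for i in range(exons_per_region):
            elements.append(("exon", exon_length))
            if i < introns_per_region:
                elements.append(("intron", intron_length))
        elements.append(("intergenic", intergenic_length))
    return ChromosomeLayout(elements)


class PiecewiseRate:
    """Piecewise-constant per-bp per-generation rate over [0, L)."""

    def __init__(self, breaks: np.ndarray, rates: np.ndarray):
        self.breaks = np.asarray(breaks, dtype=float)
        self.rates = np.asarray(rates, dtype=float)
        if self.breaks.size != self.rates.size + 1:
            raise ValueError("need len(breaks) == len(rates) + 1")
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")
        widths = np.diff(self.breaks)
        self.mass = float(np.sum(widths * self.rates))
        self._cum = np.concatenate([[0.0], np.cumsum(widths * self.rates)])

    @classmethod
    def uniform(cls, length: int, rate: float) -> "PiecewiseRate":
        return cls(np.array([0.0, float(length)]), np.array([rate]))

    @property
    def length(self) -> float:
        return float(self.breaks[-1])

    @property
    def mean_rate(self) -> float:
        return self.mass / self.length

    def sample_positions(self, rng: np.random.Generator, n: int) -> np.ndarray:
        """Positions drawn with density proportional to the local rate."""
        if self.mass == 0 or n == 0:
            return np.zeros(0)
        u = rng.uniform(0.0, self.mass, size=n)
        seg = np.clip(np.searchsorted(self._cum, u, side="right") - 1, 0, self.rates.size - 1)
        rate = np.where(self.rates[seg] > 0, self.rates[seg], np.inf)
        pos = self.breaks[seg] + (u - self._cum[seg]) / rate
        return np.minimum(pos, np.nextafter(self.length, 0.0))


def replicate_rate_map(
    length: int, mean_rate: float, rng: np.random.Generator, n_segments: int = 20,
    rel_spread: float = 1.0,
) -> PiecewiseRate:
    """Per-replicate heterogeneous map: segment rates uniform around the mean,
    rescaled so the map's length-weighted mean equals ``mean_rate`` exactly."""
    breaks = np.linspace(0.0, float(length), n_segments + 1)
    lo = max(0.0, 1.0 - rel_spread / 2)
    raw = rng.uniform(lo, 1.0 + rel_spread / 2, size=n_segments)
    raw *= mean_rate / raw.mean()
    return PiecewiseRate(breaks, raw)


@dataclass
class SweepConfig:
    """A conditioned single-sweep scenario.

    model 1: beneficial introduced into AFR immediately after burn-in, must
    fix in all four sampled populations; model 2: into EURASI at the OOA
    split, must fix in EUR/EAS/SAS; model 3: into EUR at its split, must fix
    in EUR.  ``two_ns`` is 2·N_ref·s_b.
    """

    model_id: int
    two_ns: float = 1_000.0
    restart_cap: int = 10_000
    position: int | None = None  # default: centre of the central exon

    _INTRO = {1: "AFR", 2: "EURASI", 3: "EUR"}
    _CONDITION = {1: ("AFR", "EUR", "EAS", "SAS"), 2: ("EUR", "EAS", "SAS"), 3: ("EUR",)}

    def __post_init__(self):
        if self.model_id not in (1, 2, 3):
            raise ValueError("model_id must be 1, 2 or 3")

    @property
    def introduction_population(self) -> str:
        return self._INTRO[self.model_id]

    @property
    def conditioning_populations(self) -> tuple[str, ...]:
        return self._CONDITION[self.model_id]


@dataclass
class ForwardSimResult:
    samples: dict[str, HaplotypeSample]
    fixations: pd.DataFrame  # position, s, generation, element (post-burn-in)
    restarts: int = 0
    sweep_position: int | None = None
    sweep_fixed_in: tuple[str, ...] = ()
    layout: ChromosomeLayout | None = None

    def divergence(self, element: str | None = "exon") -> float:
        """Post-burn-in fixations per bp of the given element class (or the
        whole chromosome when element is None)."""
        if self.layout is None:
            raise ValueError("result has no layout")
        if element is None:
            denom = self.layout.total_length
            count = len(self.fixations)
        else:
            denom = sum(l for k, l in self.layout.elements if k == element)
            count = int((self.fixations["element"] == element).sum())
        if denom == 0:
            raise ValueError(f"layout has no {element} bases")
        return count / denom

    def substitution_positions(self) -> np.ndarray:
        return self.fixations["position"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# demographic schedule for forward runs

@dataclass
class _PopPlan:
    name: str
    founded: int  # forward generation of founding (0 for AFR)
    bottleneck_until: int
    bottleneck_size: float
    base_size: float
    growth_rate: float = 0.0
    growth_from: int | None = None
    extinct: int | None = None
    source: str | None = None

    def size_at(self, gen: int) -> int:
        if gen < self.bottleneck_until:
            n = self.bottleneck_size
        elif self.growth_from is not None and gen >= self.growth_from:
            n = self.base_size * np.exp(self.growth_rate * (gen - self.growth_from))
        else:
            n = self.base_size
        return max(2, int(round(n)))


def build_forward_plans(
    model: OOADemography, burn_in: int, divergence_generations: int
) -> dict[str, _PopPlan]:
    """Translate the (scaled) demographic model into forward-time population
    plans on the generation axis [0, burn_in + divergence_generations]."""
    validate_model(model)
    T = divergence_generations
    if model.tau_OOA >= T:
        raise ValueError("tau_OOA exceeds the divergence window")
    end = burn_in + T

    def g(tau: float) -> int:
        return int(round(end - tau))

    dur = int(round(model.bottleneck_duration))
    plans = {
        "AFR": _PopPlan("AFR", 0, 0, model.N_AFR_anc, model.N_AFR_anc,
                        model.r_AFR, g(model.tau_BANTU)),
        "EURASI": _PopPlan(
            "EURASI", g(model.tau_OOA), min(g(model.tau_OOA) + dur, end),
            model.B_EURASI * model.N_AFR_anc, model.N_EURASI,
            extinct=g(min(model.tau_EUR, model.tau_EAS, model.tau_SAS)), source="AFR"),
    }
    for pop, B, N, r, tau in (
        ("EUR", model.B_EUR, model.N_EUR, model.r_EUR, model.tau_EUR),
        ("EAS", model.B_EAS, model.N_EAS, model.r_EAS, model.tau_EAS),
        ("SAS", model.B_SAS, model.N_SAS, model.r_SAS, model.tau_SAS),
    ):
        founded = g(tau)
        until = min(founded + dur, end)
        plans[pop] = _PopPlan(pop, founded, until, B * model.N_EURASI, N, r, until,
                              source="EURASI")
    return plans


def _migration_windows(model: OOADemography, burn_in: int, T: int) -> list[tuple]:
    """(pop_a, pop_b, rate, g_start, g_end) for each active migration pair."""
    end = burn_in + T

    def g(tau: float) -> int:
        return int(round(end - tau))

    min_tau = min(model.tau_EUR, model.tau_EAS, model.tau_SAS)
    taus = {"EUR": model.tau_EUR, "EAS": model.tau_EAS, "SAS": model.tau_SAS}
    win = [("AFR", "EURASI", model.m_AFR_EURASI, g(model.tau_OOA), g(min_tau))]
    for a, b, m in (
        ("AFR", "EUR", model.m_AFR_EUR), ("AFR", "EAS", model.m_AFR_EAS),
        ("AFR", "SAS", model.m_AFR_SAS), ("EUR", "EAS", model.m_EUR_EAS),
        ("EUR", "SAS", model.m_EUR_SAS), ("EAS", "SAS", model.m_EAS_SAS),
    ):
        start = max(g(taus.get(a, np.inf)) if a in taus else 0,
                    g(taus[b]) if b in taus else 0)
        win.append((a, b, m, start, end))
    return [w for w in win if w[2] > 0 and w[4] > w[3]]


# ---------------------------------------------------------------------------
# engine

class WrightFisherSimulator:
    """Multi-population diploid Wright–Fisher engine over one chromosome."""

    def __init__(
        self,
        layout: ChromosomeLayout,
        dfe: DFEModel | None,
        mu: PiecewiseRate | float,
        rec: PiecewiseRate | float,
        n_ref: int,
        model: OOADemography | None = None,
        burn_in_multiplier: float = 10.0,
        divergence_generations: int | None = None,
        seed: int | None = None,
    ):
        self.layout = layout
        self.dfe = dfe
        L = layout.total_length
        self.mu = mu if isinstance(mu, PiecewiseRate) else PiecewiseRate.uniform(L, mu)
        self.rec = rec if isinstance(rec, PiecewiseRate) else PiecewiseRate.uniform(L, rec)
        self.n_ref = int(n_ref)
        self.model = model
        self.rng = np.random.default_rng(seed)
        self.burn_in = int(round(burn_in_multiplier * n_ref))
        self.T = int(divergence_generations) if divergence_generations is not None else 0
        self.end_gen = self.burn_in + self.T

        if model is not None:
            self.plans = build_forward_plans(model, self.burn_in, self.T)
            self.migration = _migration_windows(model, self.burn_in, self.T)
        else:
            self.plans = {"AFR": _PopPlan("AFR", 0, 0, n_ref, n_ref)}
            self.migration = []

        # exon membership lookup
        ex = layout.intervals("exon")
        self._exon_flat = ex.reshape(-1) if ex.size else np.zeros(0, dtype=np.int64)

        self.gen = 0
        self.positions = np.zeros(0, dtype=np.int64)
        self.sel = np.zeros(0, dtype=float)
        self.elem = np.zeros(0, dtype=np.int8)
        self.used: set[int] = set()
        self.fixed_log: list[dict] = []
        n0 = self.plans["AFR"].size_at(0)
        self.pops: dict[str, np.ndarray] = {
            "AFR": np.zeros((2 * n0, 0), dtype=np.uint8)
        }

    # -- helpers ---------------------------------------------------------

    def _is_exonic(self, positions: np.ndarray) -> np.ndarray:
        if self._exon_flat.size == 0:
            return np.zeros(len(positions), dtype=bool)
        idx = np.searchsorted(self._exon_flat, positions, side="right")
        return idx % 2 == 1

    def _fitness_probs(self, haps: np.ndarray) -> np.ndarray | None:
        sel_idx = np.flatnonzero(self.sel != 0.0)
        n_ind = haps.shape[0] // 2
        if sel_idx.size == 0:
            return None
        h = self.dfe.h if self.dfe is not None else 0.5
        s = self.sel[sel_idx]
        log_het = np.log(np.maximum(1.0 + h * s, 1e-12))
        log_hom = np.log(np.maximum(1.0 + s, 1e-12))
        sub = haps[:, sel_idx]
        dosage = (sub[0::2].astype(np.float64) + sub[1::2])
        logw = dosage @ log_het + (dosage == 2.0) @ (log_hom - 2.0 * log_het)
        logw -= logw.max()
        w = np.exp(logw)
        tot = w.sum()
        if tot <= 0:
            return np.full(n_ind, 1.0 / n_ind)
        return w / tot

    def _make_gametes(self, haps: np.ndarray, parent_rows: np.ndarray) -> np.ndarray:
        """One gamete per entry of parent_rows (individual indices)."""
        rng = self.rng
        n_g = parent_rows.size
        start_hap = rng.integers(0, 2, size=n_g)
        rows = 2 * parent_rows + start_hap
        gam = haps[rows].copy()
        n_cx = rng.poisson(self.rec.mass, size=n_g)
        for i in np.flatnonzero(n_cx):
            cx = np.sort(self.rec.sample_positions(rng, n_cx[i]))
            parity = np.searchsorted(cx, self.positions, side="right") % 2
            other = haps[2 * parent_rows[i] + (1 - start_hap[i])]
            gam[i] = np.where(parity == 0, gam[i], other)
        return gam

    def _add_mutations(self, offspring: dict[str, np.ndarray]) -> None:
        rng = self.rng
        total_haps = sum(m.shape[0] for m in offspring.values())
        n_new = rng.poisson(total_haps * self.mu.mass)
        if n_new == 0:
            return
        pos_f = self.mu.sample_positions(rng, n_new)
        new_pos = []
        for p in np.floor(pos_f).astype(np.int64):
            tries = 0
            while (int(p) in self.used or p in new_pos) and tries < 20:
                p = int(np.floor(self.mu.sample_positions(rng, 1)[0]))
                tries += 1
            if int(p) in self.used or p in new_pos:
                continue  # site saturated; drop (infinite-sites rejection)
            new_pos.append(int(p))
        if not new_pos:
            return
        new_pos = np.asarray(new_pos, dtype=np.int64)
        exonic = self._is_exonic(new_pos)
        s_new = np.zeros(new_pos.size)
        if self.dfe is not None:
            for i in np.flatnonzero(exonic):
                s_new[i], _ = draw_fitness_effect(self.dfe, rng)
        elem_new = self.layout.element_at(new_pos).astype(np.int8)
        # carrier haplotype per mutation, uniform over all offspring haplotypes
        carrier = rng.integers(0, total_haps, size=new_pos.size)
        self.positions = np.concatenate([self.positions, new_pos])
        self.sel = np.concatenate([self.sel, s_new])
        self.elem = np.concatenate([self.elem, elem_new])
        self.used.update(int(p) for p in new_pos)
        offset = 0
        for name in offspring:
            m = offspring[name]
            block = np.zeros((m.shape[0], new_pos.size), dtype=np.uint8)
            local = carrier - offset
            sel_rows = (local >= 0) & (local < m.shape[0])
            block[local[sel_rows], np.flatnonzero(sel_rows)] = 1
            offspring[name] = np.concatenate([m, block], axis=1)
            offset += m.shape[0]

    def _prune(self) -> None:
        if self.positions.size == 0:
            return
        total = sum(m.shape[0] for m in self.pops.values())
        counts = np.zeros(self.positions.size, dtype=np.int64)
        for m in self.pops.values():
            counts += m.sum(axis=0, dtype=np.int64)
        lost = counts == 0
        fixed = counts == total
        if fixed.any() and self.gen > self.burn_in:
            for j in np.flatnonzero(fixed):
                self.fixed_log.append(dict(
                    position=int(self.positions[j]), s=float(self.sel[j]),
                    generation=int(self.gen),
                    element=_ELEMENT_NAMES[int(self.elem[j])],
                ))
        drop = lost | fixed
        if drop.any():
            keep = ~drop
            for p in self.positions[lost]:
                self.used.discard(int(p))  # lost sites can be hit again later
            self.positions = self.positions[keep]
            self.sel = self.sel[keep]
            self.elem = self.elem[keep]
            for name in self.pops:
                self.pops[name] = self.pops[name][:, keep]

    # -- generation loop -------------------------------------------------

    def _founding(self) -> None:
        for name, plan in self.plans.items():
            if plan.founded == self.gen and name not in self.pops and plan.source:
                src = self.pops[plan.source]
                n_found = plan.size_at(self.gen)
                n_src = src.shape[0] // 2
                if n_found > n_src:
                    raise ValueError(f"founding size of {name} exceeds source size")
                idx = self.rng.choice(n_src, size=n_found, replace=False)
                rows = np.column_stack([2 * idx, 2 * idx + 1]).reshape(-1)
                self.pops[name] = src[rows].copy()
        for name, plan in self.plans.items():
            if plan.extinct is not None and plan.extinct == self.gen and name in self.pops:
                del self.pops[name]

    def _migrate(self, offspring: dict[str, np.ndarray]) -> None:
        active = [
            (a, b, rate) for a, b, rate, g0, g1 in self.migration
            if g0 < self.gen <= g1 and a in offspring and b in offspring
        ]
        if not active:
            return
        # migrants are drawn from pre-migration copies of both populations
        involved = {p for pair in active for p in pair[:2]}
        pre = {k: offspring[k].copy() for k in involved}
        for a, b, rate in active:
            for dst, src in ((a, b), (b, a)):
                n_dst = offspring[dst].shape[0] // 2
                n_src = pre[src].shape[0] // 2
                n_mig = min(self.rng.poisson(rate * n_dst), n_dst, n_src)
                if n_mig == 0:
                    continue
                into = self.rng.choice(n_dst, size=n_mig, replace=False)
                from_ = self.rng.choice(n_src, size=n_mig, replace=False)
                rows_i = np.column_stack([2 * into, 2 * into + 1]).reshape(-1)
                rows_f = np.column_stack([2 * from_, 2 * from_ + 1]).reshape(-1)
                offspring[dst][rows_i] = pre[src][rows_f]

    def step(self) -> None:
        """Advance one generation."""
        self.gen += 1
        self._founding()
        offspring: dict[str, np.ndarray] = {}
        for name, haps in self.pops.items():
            plan = self.plans[name]
            n_next = plan.size_at(self.gen)
            probs = self._fitness_probs(haps)
            n_par = haps.shape[0] // 2
            parents = self.rng.choice(n_par, size=(n_next, 2), p=probs)
            gam_a = self._make_gametes(haps, parents[:, 0])
            gam_b = self._make_gametes(haps, parents[:, 1])
            child = np.empty((2 * n_next, self.positions.size), dtype=np.uint8)
            child[0::2] = gam_a
            child[1::2] = gam_b
            offspring[name] = child
        self._migrate(offspring)
        self._add_mutations(offspring)
        self.pops = offspring
        self._prune()

    def advance(self, until: int) -> None:
        while self.gen < until:
            self.step()

    # -- state management for conditioned restarts -----------------------

    def snapshot(self) -> dict:
        return dict(
            gen=self.gen,
            positions=self.positions.copy(), sel=self.sel.copy(), elem=self.elem.copy(),
            used=set(self.used), fixed_log=copy.deepcopy(self.fixed_log),
            pops={k: v.copy() for k, v in self.pops.items()},
        )

    def restore(self, snap: dict) -> None:
        self.gen = snap["gen"]
        self.positions = snap["positions"].copy()
        self.sel = snap["sel"].copy()
        self.elem = snap["elem"].copy()
        self.used = set(snap["used"])
        self.fixed_log = copy.deepcopy(snap["fixed_log"])
        self.pops = {k: v.copy() for k, v in snap["pops"].items()}

    def introduce_mutation(self, population: str, position: int, s: float) -> None:
        """Add a single-copy mutation at ``position`` in a random haplotype."""
        if int(position) in self.used:
            raise ValueError(f"position {position} already in use")
        self.positions = np.concatenate([self.positions, [int(position)]])
        self.sel = np.concatenate([self.sel, [float(s)]])
        self.elem = np.concatenate(
            [self.elem, self.layout.element_at(np.array([position])).astype(np.int8)])
        self.used.add(int(position))
        for name, m in self.pops.items():
            col = np.zeros((m.shape[0], 1), dtype=np.uint8)
            if name == population:
                col[self.rng.integers(0, m.shape[0]), 0] = 1
            self.pops[name] = np.concatenate([m, col], axis=1)

    def allele_state(self, position: int) -> dict[str, float] | str:
        """Frequency per population, or 'fixed'/'lost' if no longer segregating."""
        j = np.flatnonzero(self.positions == position)
        if j.size == 0:
            if any(f["position"] == position for f in self.fixed_log):
                return "fixed"
            return "lost"
        j = int(j[0])
        return {name: float(m[:, j].mean()) for name, m in self.pops.items()}

    def sample(self, sample_sizes: dict[str, int]) -> dict[str, HaplotypeSample]:
        out = {}
        order = np.argsort(self.positions, kind="stable")
        for name, n in sample_sizes.items():
            if name not in self.pops:
                raise ValueError(f"population {name!r} not extant at sampling time")
            m = self.pops[name]
            n_ind = m.shape[0] // 2
            if n > n_ind:
                raise ValueError(f"sample size {n} exceeds population size {n_ind}")
            idx = self.rng.choice(n_ind, size=n, replace=False)
            rows = np.column_stack([2 * idx, 2 * idx + 1]).reshape(-1)
            geno = m[rows][:, order]
            pos = self.positions[order].astype(float)
            # drop sites monomorphic in nobody: keep all segregating-in-meta sites
            out[name] = HaplotypeSample(
                positions=pos, genotypes=geno,
                populations=np.repeat(name, 2 * n), length=self.layout.total_length)
        return out

    def result(
        self, sample_sizes: dict[str, int], restarts: int = 0,
        sweep_position: int | None = None, sweep_fixed_in: tuple[str, ...] = (),
    ) -> ForwardSimResult:
        fixations = pd.DataFrame(self.fixed_log,
                                 columns=["position", "s", "generation", "element"])
        return ForwardSimResult(
            samples=self.sample(sample_sizes), fixations=fixations, restarts=restarts,
            sweep_position=sweep_position, sweep_fixed_in=sweep_fixed_in,
            layout=self.layout)


# ---------------------------------------------------------------------------
# high-level runners

def run_forward(
    layout: ChromosomeLayout,
    dfe: DFEModel | None,
    mu: PiecewiseRate | float,
    rec: PiecewiseRate | float,
    n_ref: int,
    divergence_generations: int,
    sample_sizes: dict[str, int],
    model: OOADemography | None = None,
    burn_in_multiplier: float = 10.0,
    seed: int | None = None,
) -> ForwardSimResult:
    """Burn-in then a divergence window with the demographic events scheduled
    at their times before present; post-burn-in fixations are logged."""
    sim = WrightFisherSimulator(layout, dfe, mu, rec, n_ref, model,
                                burn_in_multiplier, divergence_generations, seed)
    sim.advance(sim.end_gen)
    return sim.result(sample_sizes)


def run_recurrent_sweeps(
    layout: ChromosomeLayout,
    dfe: DFEModel,
    beneficial_rate: float,
    beneficial_range: tuple[float, float],
    mu: PiecewiseRate | float,
    rec: PiecewiseRate | float,
    n_ref: int,
    divergence_generations: int,
    sample_sizes: dict[str, int],
    model: OOADemography | None = None,
    burn_in_multiplier: float = 10.0,
    seed: int | None = None,
) -> ForwardSimResult:
    """As run_forward, with a beneficial DFE class of the given rate taken out
    of the effectively neutral class f0."""
    dfe_b = dfe.with_beneficial(beneficial_rate, beneficial_range) if beneficial_rate > 0 else dfe
    return run_forward(layout, dfe_b, mu, rec, n_ref, divergence_generations,
                       sample_sizes, model, burn_in_multiplier, seed)


def run_conditioned_sweep(
    cfg: SweepConfig,
    layout: ChromosomeLayout,
    dfe: DFEModel | None,
    mu: PiecewiseRate | float,
    rec: PiecewiseRate | float,
    n_ref: int,
    divergence_generations: int,
    sample_sizes: dict[str, int],
    model: OOADemography | None = None,
    burn_in_multiplier: float = 10.0,
    seed: int | None = None,
) -> ForwardSimResult:
    """Single conditioned hard sweep; restarts from the introduction-time
    state (not a fresh burn-in) until the beneficial allele is fixed in every
    conditioning population at sampling time."""
    sim = WrightFisherSimulator(layout, dfe, mu, rec, n_ref, model,
                                burn_in_multiplier, divergence_generations, seed)
    if model is None:
        intro_gen = sim.burn_in
        intro_pop = "AFR"
    else:
        intro_pop = cfg.introduction_population
        if cfg.model_id == 1:
            intro_gen = sim.burn_in
        elif cfg.model_id == 2:
            intro_gen = sim.plans["EURASI"].founded
        else:
            intro_gen = sim.plans["EUR"].founded
    sim.advance(intro_gen)

    if cfg.position is not None:
        position = int(cfg.position)
    else:
        ex = layout.intervals("exon")
        if len(ex):  # centre of the central exon; else chromosome midpoint
            mid = ex[len(ex) // 2]
            position = int((mid[0] + mid[1]) // 2)
        else:
            position = layout.total_length // 2
    s_b = cfg.two_ns / (2.0 * n_ref)
    snap = sim.snapshot()

    conditioning = cfg.conditioning_populations if model is not None else ("AFR",)
    for attempt in range(cfg.restart_cap + 1):
        sim.introduce_mutation(intro_pop, position, s_b)
        ok = True
        while sim.gen < sim.end_gen:
            sim.step()
            state = sim.allele_state(position)
            if state == "lost":
                ok = False
                break
        if ok:
            state = sim.allele_state(position)
            if state == "fixed":
                fixed_in = tuple(sorted(sim.pops))
            elif isinstance(state, dict):
                fixed_in = tuple(p for p, f in state.items() if f >= 1.0)
            else:
                fixed_in = ()
            if all(p in fixed_in for p in conditioning):
                return sim.result(sample_sizes, restarts=attempt,
                                  sweep_position=position, sweep_fixed_in=fixed_in)
        sim.restore(snap)
    raise RuntimeError(
        f"beneficial mutation failed to fix in {conditioning} within "
        f"{cfg.restart_cap} restarts"
    )
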