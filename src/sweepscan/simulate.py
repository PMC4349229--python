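"""Synthetic phased three-population haplotype data.

Two generators share one demographic parameterization (two splits, a
domestication bottleneck and a breed-formation bottleneck, symmetric
migration between the two breeds after their split):

- a structured-coalescent mode without recombination (infinite sites,
  mutations dropped on the genealogy), and
- a discrete-generation forward Wright-Fisher mode with uniform
  recombination, finite-sites biallelic mutation (recurrent hits rejected)
  and optional planted sweeps under additive viability selection
  (fitness 1, 1+s, 1+2s).

All randomness flows from one integer seed through
``numpy.random.SeedSequence`` spawning; fixed seeds give byte-identical
replicates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from sweepscan.io import GeneModel, HaplotypeSet, QtlInterval, QTL_CATEGORIES

DEFAULT_LABELS = ("breed1", "breed2", "outgroup")

# population indices used by the coalescent engine
_B1, _B2, _OUT = 0, 1, 2


@dataclass
class DemographyModel:
    """Two-split, two-bottleneck three-population demography.

    Times are in generations before present; sizes are diploid. The first
    bottleneck (``N_bottleneck1`` for ``D_bottleneck1`` generations) starts
    at the wild/domestic split ``T_dom``; the second (``N_bottleneck2`` for
    ``D_bottleneck2``) starts at the breed split ``T_split``. ``m`` is the
    symmetric per-lineage per-generation migration probability between the
    two breeds after their split. Defaults are illustrative, not fitted
    estimates; any parameterization can be supplied.
    """

    N_anc: int = 8000
    T_dom: float = 1200.0
    T_split: float = 300.0
    N_bottleneck1: int = 800
    D_bottleneck1: float = 150.0
    N_bottleneck2: int = 80
    D_bottleneck2: float = 40.0
    N_breed: int = 1200
    m: float = 1e-3
    mu: float = 2.5e-8
    r: float = 1e-8

    def __post_init__(self) -> None:
        for name in ("N_anc", "N_bottleneck1", "N_bottleneck2", "N_breed"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("D_bottleneck1", "D_bottleneck2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.m < 1:
            raise ValueError("migration probability must be in [0, 1)")
        if not 0 <= self.T_split <= self.T_dom:
            raise ValueError("need T_dom >= T_split >= 0")
        if self.D_bottleneck1 > self.T_dom - self.T_split:
            raise ValueError("domestication bottleneck longer than its epoch")
        if self.D_bottleneck2 > self.T_split:
            raise ValueError("breed bottleneck longer than its epoch")
        if self.mu < 0 or self.r < 0:
            raise ValueError("mutation/recombination rates must be >= 0")

    @classmethod
    def panmictic(cls, n: int = 1000, mu: float = 2.5e-8) -> "DemographyModel":
        """Degenerate single-population model (both splits collapsed to 0)."""
        return cls(
            N_anc=n, T_dom=0.0, T_split=0.0,
            N_bottleneck1=n, D_bottleneck1=0.0,
            N_bottleneck2=n, D_bottleneck2=0.0,
            N_breed=n, m=0.0, mu=mu, r=0.0,
        )

    def rescaled(self, factor: float) -> "DemographyModel":
        """Shrink sizes and times by ``factor`` while boosting per-event
        rates, preserving N*mu, N*r and N*m (standard rescaling)."""
        return DemographyModel(
            N_anc=max(1, round(self.N_anc / factor)),
            T_dom=self.T_dom / factor,
            T_split=self.T_split / factor,
            N_bottleneck1=max(1, round(self.N_bottleneck1 / factor)),
            D_bottleneck1=self.D_bottleneck1 / factor,
            N_bottleneck2=max(1, round(self.N_bottleneck2 / factor)),
            D_bottleneck2=self.D_bottleneck2 / factor,
            N_breed=max(1, round(self.N_breed / factor)),
            m=min(0.999, self.m * factor),
            mu=self.mu * factor,
            r=self.r * factor,
        )

    def present_size(self, pop_index: int) -> int:
        if pop_index == _OUT:
            return self.N_anc
        if self.T_split == 0:
            return self.N_anc
        return (
            self.N_bottleneck2 if self.D_bottleneck2 >= self.T_split
            else self.N_breed
        )


@dataclass
class SweepSpec:
    """A planted sweep: additive selection with coefficient ``s`` on an
    allele introduced at ``position`` in ``target_population`` at
    ``onset_generation`` (generations before present). ``mode`` is
    ``complete`` (conditioned on fixation at sampling) or ``partial``
    (selection switches off once ``target_frequency`` is reached and the
    run is conditioned on the allele segregating near that frequency)."""

    target_population: str
    position: int
    s: float
    onset_generation: float
    mode: str = "complete"
    target_frequency: float = 0.5

    def __post_init__(self) -> None:
        if self.s <= 0:
            raise ValueError("selection coefficient must be > 0")
        if self.mode not in ("complete", "partial"):
            raise ValueError("mode must be 'complete' or 'partial'")
        if self.mode == "partial" and not 0 < self.target_frequency < 1:
            raise ValueError("partial-mode target frequency must be in (0,1)")

    def rescaled(self, factor: float) -> "SweepSpec":
        return SweepSpec(
            target_population=self.target_population,
            position=self.position,
            s=self.s * factor,
            onset_generation=self.onset_generation / factor,
            mode=self.mode,
            target_frequency=self.target_frequency,
        )


@dataclass
class GroundTruth:
    """What was planted and what happened: per-sweep final population
    frequencies, the master seed, rejection counts, and the realized
    demographic event list."""

    seed: int
    n_rejections: int
    sweeps: list[dict] = field(default_factory=list)
    events: list[str] = field(default_factory=list)

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# ---------------------------------------------------------------------------
# Structured coalescent without recombination
# ---------------------------------------------------------------------------


def _pop_size_backward(model: DemographyModel, pop: int, t: float) -> int:
    """Diploid size of coalescent population ``pop`` at backward time t."""
    if pop == _OUT or t >= model.T_dom:
        return model.N_anc
    if t >= model.T_split:  # domestic ancestor epoch (lineages sit in pop 0)
        if t >= model.T_dom - model.D_bottleneck1:
            return model.N_bottleneck1
        return model.N_anc
    if t >= model.T_split - model.D_bottleneck2:
        return model.N_bottleneck2
    return model.N_breed


def _simulate_tree(
    model: DemographyModel,
    sample_counts: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, list[list[int]]]:
    """Simulate one genealogy; returns (parent, node_time, leaf sets)."""
    n_total = sum(sample_counts)
    parent = [-1] * n_total
    node_time = [0.0] * n_total
    leaves: list[list[int]] = [[i] for i in range(n_total)]
    active: dict[int, list[int]] = {_B1: [], _B2: [], _OUT: []}
    nxt = 0
    for pop, k in zip((_B1, _B2, _OUT), sample_counts):
        active[pop] = list(range(nxt, nxt + k))
        nxt += k

    boundaries: list[tuple[float, str]] = []
    if model.D_bottleneck2 > 0:
        boundaries.append((model.T_split - model.D_bottleneck2, "size"))
    boundaries.append((model.T_split, "merge_breeds"))
    if model.D_bottleneck1 > 0:
        boundaries.append((model.T_dom - model.D_bottleneck1, "size"))
    boundaries.append((model.T_dom, "merge_wild"))
    boundaries.sort()

    t = 0.0
    bi = 0

    def apply_boundary(kind: str) -> None:
        if kind == "merge_breeds":
            active[_B1].extend(active[_B2])
            active[_B2] = []
        elif kind == "merge_wild":
            active[_OUT].extend(active[_B1])
            active[_B1] = []

    # process zero-time (degenerate) boundaries up front
    while bi < len(boundaries) and boundaries[bi][0] <= t:
        apply_boundary(boundaries[bi][1])
        bi += 1

    while sum(len(v) for v in active.values()) > 1:
        rates: list[tuple[float, str, int]] = []
        for pop, lin in active.items():
            k = len(lin)
            if k >= 2:
                rates.append(
                    (k * (k - 1) / 2.0 / (2.0 * _pop_size_backward(model, pop, t)),
                     "coal", pop)
                )
        if t < model.T_split and model.m > 0:
            for pop in (_B1, _B2):
                k = len(active[pop])
                if k and active[_B1 if pop == _B2 else _B2] is not None:
                    rates.append((k * model.m, "mig", pop))
        total = sum(r[0] for r in rates)
        t_next = boundaries[bi][0] if bi < len(boundaries) else np.inf
        if total == 0.0:
            if not np.isfinite(t_next):
                raise RuntimeError("coalescent stalled: no events possible")
            t = t_next
            apply_boundary(boundaries[bi][1])
            bi += 1
            continue
        wait = rng.exponential(1.0 / total)
        if t + wait >= t_next:
            t = t_next
            apply_boundary(boundaries[bi][1])
            bi += 1
            continue
        t += wait
        pick = rng.uniform(0.0, total)
        acc = 0.0
        for rate, kind, pop in rates:
            acc += rate
            if pick < acc:
                break
        if kind == "coal":
            lin = active[pop]
            i, j = rng.choice(len(lin), size=2, replace=False)
            a, b = lin[i], lin[j]
            new = len(parent)
            parent.append(-1)
            node_time.append(t)
            leaves.append(leaves[a] + leaves[b])
            parent[a] = new
            parent[b] = new
            active[pop] = [x for x in lin if x not in (a, b)] + [new]
        else:  # migration between the two breeds
            other = _B1 if pop == _B2 else _B2
            lin = active[pop]
            i = rng.integers(len(lin))
            active[other].append(lin.pop(i))
    return np.array(parent), np.array(node_time), leaves


def _drop_mutations(
    parent: np.ndarray,
    node_time: np.ndarray,
    leaves: list[list[int]],
    n_leaves: int,
    per_branch_rate: float,
    region_length: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Poisson mutations on branches, infinite sites over the region."""
    n_mut_per_node = np.zeros(len(parent), dtype=np.int64)
    for v in range(len(parent)):
        if parent[v] >= 0:
            blen = node_time[parent[v]] - node_time[v]
            n_mut_per_node[v] = rng.poisson(blen * per_branch_rate)
    total = int(n_mut_per_node.sum())
    if total == 0:
        return np.empty((n_leaves, 0), dtype=np.uint8), np.empty(0, np.int64)
    if total > region_length:
        raise ValueError(
            "more mutations than sites in the region; increase region_length"
        )
    positions = rng.choice(region_length, size=total, replace=False, shuffle=False)
    alleles = np.zeros((n_leaves, total), dtype=np.uint8)
    col = 0
    for v in np.flatnonzero(n_mut_per_node):
        for _ in range(n_mut_per_node[v]):
            alleles[leaves[v], col] = 1
            col += 1
    order = np.argsort(positions)
    return alleles[:, order], positions[order]


def simulate_neutral_coalescent(
    model: DemographyModel,
    samples_per_pop: dict[str, int],
    theta: float,
    n_replicates: int,
    seed: int,
    region_length: int = 1_000_000,
    labels: tuple[str, str, str] = DEFAULT_LABELS,
) -> list[HaplotypeSet]:
    """Neutral replicates without recombination under the structured
    coalescent.

    ``samples_per_pop`` maps each of the three labels (breed1, breed2,
    outgroup order given by ``labels``) to a diploid sample count; each
    replicate carries 2n haplotype rows per population. ``theta`` is the
    scaled mutation rate of the whole locus (4 * N_anc * mu * L); mutations
    fall on the genealogy at rate theta / (4 N_anc) per branch generation
    under infinite sites.
    """
    if theta <= 0:
        raise ValueError("theta must be positive")
    counts = tuple(2 * samples_per_pop.get(lbl, 0) for lbl in labels)
    if sum(c >= 2 for c in counts) == 0:
        raise ValueError("need at least one population with >= 1 diploid")
    for pop, c in zip((_B1, _B2, _OUT), counts):
        if c > 2 * _pop_size_backward(model, pop, 0.0):
            raise ValueError(
                "sample count exceeds 2x population size at sampling time"
            )
    per_branch = theta / (4.0 * model.N_anc)
    pop_labels = np.repeat(
        [lbl for lbl in labels], [c for c in counts]
    )
    out: list[HaplotypeSet] = []
    for child_seed in np.random.SeedSequence(seed).spawn(n_replicates):
        rng = np.random.default_rng(child_seed)
        parent, node_time, leaves = _simulate_tree(model, counts, rng)
        alleles, positions = _drop_mutations(
            parent, node_time, leaves, sum(counts), per_branch,
            region_length, rng,
        )
        out.append(
            HaplotypeSet(
                alleles=alleles,
                chrom=np.full(positions.size, "1"),
                positions=positions,
                populations=pop_labels,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Forward Wright-Fisher with recombination and planted sweeps
# ---------------------------------------------------------------------------


class _ForwardState:
    """Mutable forward-simulation state: aligned per-population haplotype
    matrices over one shared site registry kept sorted by position."""

    def __init__(self, region_length: int):
        self.L = region_length
        self.positions = np.empty(0, dtype=np.int64)
        self.occupied: set[int] = set()
        self.pops: dict[str, np.ndarray] = {}

    def add_sites(self, positions: np.ndarray, alleles_by_pop: dict[str, np.ndarray]) -> None:
        order = np.argsort(positions, kind="stable")
        positions = positions[order]
        at = np.searchsorted(self.positions, positions)
        n_old = self.positions.size
        k = positions.size
        dest_new = at + np.arange(k)
        new_positions = np.empty(n_old + k, dtype=np.int64)
        self.occupied.update(int(p) for p in positions)
        for name, mat in self.pops.items():
            extra = alleles_by_pop.get(name)
            if extra is not None:
                extra = extra[:, order]
            new = np.empty((mat.shape[0], n_old + k), dtype=np.uint8)
            # copy old columns block-wise between insertion points
            prev = 0
            for i, a in enumerate(at):
                new[:, prev + i : a + i] = mat[:, prev:a]
                new[:, a + i] = 0 if extra is None else extra[:, i]
                prev = a
            new[:, prev + k :] = mat[:, prev:]
            self.pops[name] = new
        prev = 0
        for i, a in enumerate(at):
            new_positions[prev + i : a + i] = self.positions[prev:a]
            new_positions[a + i] = positions[i]
            prev = a
        new_positions[prev + k :] = self.positions[prev:]
        self.positions = new_positions

    def site_index(self, position: int) -> int:
        i = int(np.searchsorted(self.positions, position))
        if i < self.positions.size and self.positions[i] == position:
            return i
        return -1

    def prune(self, keep_positions: set[int]) -> None:
        """Drop sites monomorphic across all populations."""
        if self.positions.size == 0:
            return
        total = np.zeros(self.positions.size, dtype=np.int64)
        n_hap = 0
        for mat in self.pops.values():
            total += mat.sum(axis=0, dtype=np.int64)
            n_hap += mat.shape[0]
        keep = (total > 0) & (total < n_hap)
        for i, p in enumerate(self.positions):
            if int(p) in keep_positions:
                keep[i] = True
        if keep.all():
            return
        for p in self.positions[~keep]:
            self.occupied.discard(int(p))
        self.positions = self.positions[keep]
        for name in self.pops:
            self.pops[name] = np.ascontiguousarray(self.pops[name][:, keep])


def _gametes(
    rng: np.random.Generator,
    parents: np.ndarray,
    parent_idx: np.ndarray,
    r: float,
    L: int,
    positions: np.ndarray,
) -> np.ndarray:
    """One gamete per entry of ``parent_idx`` (diploid parent indices).

    ``positions`` must be sorted; crossovers are applied as alternating
    segment copies between the parent's two haplotypes.
    """
    n = parent_idx.size
    which = rng.integers(0, 2, size=n)
    out = parents[2 * parent_idx + which]  # fancy indexing copies
    if r > 0 and positions.size:
        n_cross = rng.poisson(r * (L - 1), size=n)
        total = int(n_cross.sum())
        if total:
            # all crossover points located in one vectorized pass
            all_cuts = np.searchsorted(positions, rng.uniform(0, L, size=total))
            offsets = np.concatenate([[0], np.cumsum(n_cross)])
            for g in np.flatnonzero(n_cross):
                cuts = np.sort(all_cuts[offsets[g] : offsets[g + 1]])
                hap_b = parents[2 * parent_idx[g] + 1 - which[g]]
                row = out[g]
                # copy every odd-parity segment from the other haplotype
                for j in range(0, cuts.size, 2):
                    lo = cuts[j]
                    hi = cuts[j + 1] if j + 1 < cuts.size else positions.size
                    row[lo:hi] = hap_b[lo:hi]
    return out


def _selection_weights(
    mat: np.ndarray, site: int, s: float
) -> np.ndarray:
    g = mat[0::2, site].astype(np.float64) + mat[1::2, site]
    w = 1.0 + s * g
    return w / w.sum()


def _next_generation(
    rng: np.random.Generator,
    state: _ForwardState,
    dest: str,
    sources: list[tuple[str, float]],
    n_children: int,
    r: float,
    fitness_site_s: dict[str, tuple[int, float]],
) -> np.ndarray:
    """Children matrix for ``dest``: each child draws both gametes from one
    source population chosen by the (population, probability) mixture."""
    probs = np.array([p for _, p in sources])
    src_choice = rng.choice(len(sources), size=n_children, p=probs / probs.sum())
    chunks = []
    for si, (src, _) in enumerate(sources):
        k = int((src_choice == si).sum())
        if k == 0:
            continue
        parents = state.pops[src]
        n_parents = parents.shape[0] // 2
        sel = fitness_site_s.get(src)
        if sel is not None:
            w = _selection_weights(parents, sel[0], sel[1])
            idx = rng.choice(n_parents, size=2 * k, p=w)
        else:
            idx = rng.integers(0, n_parents, size=2 * k)
        chunks.append(_gametes(rng, parents, idx, r, state.L, state.positions))
    return np.vstack(chunks) if chunks else np.empty((0, state.positions.size), np.uint8)


def _forward_attempt(
    model: DemographyModel,
    sweeps: list[SweepSpec],
    region_length: int,
    rng: np.random.Generator,
    labels: tuple[str, str, str],
) -> tuple[_ForwardState, list[dict], list[str]]:
    b1, b2, outg = labels
    T_dom, T_split = int(round(model.T_dom)), int(round(model.T_split))
    events: list[str] = []
    state = _ForwardState(region_length)

    # standing variation of the wild ancestor from a panmictic coalescent
    if model.mu > 0:
        theta = 4.0 * model.N_anc * model.mu * region_length
        anc = DemographyModel.panmictic(model.N_anc, model.mu)
        parent, node_time, leaves = _simulate_tree(
            anc, (0, 0, 2 * model.N_anc), rng
        )
        alleles, positions = _drop_mutations(
            parent, node_time, leaves, 2 * model.N_anc,
            theta / (4.0 * model.N_anc), region_length, rng,
        )
    else:
        alleles = np.empty((2 * model.N_anc, 0), dtype=np.uint8)
        positions = np.empty(0, dtype=np.int64)
    state.positions = positions
    state.occupied = {int(p) for p in positions}
    state.pops[outg] = alleles
    events.append(f"t={T_dom}: ancestral population initialized (N={model.N_anc})")

    def dom_size(t: int) -> int:
        return (
            model.N_bottleneck1
            if t > model.T_dom - model.D_bottleneck1
            else model.N_anc
        )

    def breed_size(t: int) -> int:
        return (
            model.N_bottleneck2
            if t > model.T_split - model.D_bottleneck2
            else model.N_breed
        )

    sweep_state = [
        {"spec": sw, "active": False, "introduced": False} for sw in sweeps
    ]

    def fitness_map() -> dict[str, tuple[int, float]]:
        fm: dict[str, tuple[int, float]] = {}
        for ss in sweep_state:
            if ss["active"]:
                idx = state.site_index(ss["spec"].position)
                if idx >= 0:
                    fm[ss["spec"].target_population] = (idx, ss["spec"].s)
        return fm

    have_domestic = T_dom > T_split
    if have_domestic:
        state.pops["__domestic__"] = _next_generation(
            rng, state, "__domestic__", [(outg, 1.0)], dom_size(T_dom), model.r, {}
        )
        events.append(f"t={T_dom}: domestic lineage founded (N={dom_size(T_dom)})")

    breeds_exist = False
    for t in range(T_dom - 1, -1, -1):
        fm = fitness_map()
        new_pops: dict[str, np.ndarray] = {}
        new_pops[outg] = _next_generation(
            rng, state, outg, [(outg, 1.0)], model.N_anc, model.r, fm
        )
        if t >= T_split and have_domestic:
            new_pops["__domestic__"] = _next_generation(
                rng, state, "__domestic__", [("__domestic__", 1.0)],
                dom_size(t), model.r, fm,
            )
        elif not breeds_exist:
            src = "__domestic__" if have_domestic else outg
            for b in (b1, b2):
                new_pops[b] = _next_generation(
                    rng, state, b, [(src, 1.0)], breed_size(t), model.r, fm
                )
            breeds_exist = True
            events.append(
                f"t={t}: breeds founded from {src} (N={breed_size(t)} each)"
            )
        else:
            for b, other in ((b1, b2), (b2, b1)):
                srcs = [(b, 1.0 - model.m), (other, model.m)] if model.m > 0 else [(b, 1.0)]
                new_pops[b] = _next_generation(
                    rng, state, b, srcs, breed_size(t), model.r, fm
                )
        state.pops = new_pops

        # introduce sweeps scheduled for this generation
        for ss in sweep_state:
            sw = ss["spec"]
            if not ss["introduced"] and t == int(round(sw.onset_generation)):
                if sw.target_population not in state.pops:
                    raise ValueError(
                        f"sweep onset t={t} precedes the existence of "
                        f"{sw.target_population!r}"
                    )
                idx = state.site_index(sw.position)
                if idx < 0:
                    state.add_sites(
                        np.array([sw.position], dtype=np.int64), {}
                    )
                    idx = state.site_index(sw.position)
                mat = state.pops[sw.target_population]
                mat[rng.integers(mat.shape[0]), idx] = 1
                ss.update(introduced=True, active=True)
                events.append(
                    f"t={t}: sweep allele introduced at {sw.position} in "
                    f"{sw.target_population} (s={sw.s}, mode={sw.mode})"
                )

        # partial sweeps: stop selecting once the target frequency is reached
        for ss in sweep_state:
            sw = ss["spec"]
            if ss["active"] and sw.mode == "partial":
                mat = state.pops[sw.target_population]
                idx = state.site_index(sw.position)
                if idx >= 0 and mat[:, idx].mean() >= sw.target_frequency:
                    ss["active"] = False
                    events.append(
                        f"t={t}: sweep at {sw.position} reached target "
                        f"frequency; selection off"
                    )

        # new mutations (finite sites, recurrent hits rejected)
        if model.mu > 0:
            new_positions: list[int] = []
            assignments: list[tuple[str, int]] = []
            seen_batch: set[int] = set()
            for name, mat in state.pops.items():
                n_new = rng.poisson(mat.shape[0] * model.mu * region_length)
                if not n_new:
                    continue
                cand = rng.integers(region_length, size=n_new)
                rows_hit = rng.integers(mat.shape[0], size=n_new)
                for p, row in zip(cand.tolist(), rows_hit.tolist()):
                    if p in state.occupied or p in seen_batch:
                        continue  # recurrent hit rejected
                    seen_batch.add(p)
                    new_positions.append(p)
                    assignments.append((name, row))
            if new_positions:
                cols: dict[str, np.ndarray] = {}
                for (name, row), j in zip(assignments, range(len(new_positions))):
                    col = cols.setdefault(
                        name,
                        np.zeros(
                            (state.pops[name].shape[0], len(new_positions)),
                            dtype=np.uint8,
                        ),
                    )
                    col[row, j] = 1
                # site registry is append-only, so sweep site indices hold
                state.add_sites(np.array(new_positions, dtype=np.int64), cols)

        if t % 10 == 0:
            keep = {ss["spec"].position for ss in sweep_state if ss["introduced"]}
            state.prune(keep)

    truth_sweeps = []
    for ss in sweep_state:
        sw = ss["spec"]
        idx = state.site_index(sw.position)
        freqs = {}
        for name, mat in state.pops.items():
            if name.startswith("__"):
                continue
            freqs[name] = float(mat[:, idx].mean()) if idx >= 0 else 0.0
        truth_sweeps.append(
            {
                "position": sw.position,
                "target_population": sw.target_population,
                "s": sw.s,
                "mode": sw.mode,
                "onset_generation": sw.onset_generation,
                "final_frequency": freqs,
            }
        )
    return state, truth_sweeps, events


def _sweep_accepted(sweeps_truth: list[dict], freq_tolerance: float) -> bool:
    for tr in sweeps_truth:
        f = tr["final_frequency"][tr["target_population"]]
        if tr["mode"] == "complete":
            if f < 1.0:
                return False
        else:
            if not 0.0 < f < 1.0:
                return False
            target = tr.get("target_frequency", 0.5)
            if abs(f - target) > freq_tolerance:
                return False
    return True


def simulate_forward_wf(
    model: DemographyModel,
    sweeps: list[SweepSpec],
    region_length: int,
    samples_per_pop: dict[str, int],
    seed: int,
    labels: tuple[str, str, str] = DEFAULT_LABELS,
    rejection_cap: int = 1000,
    freq_tolerance: float = 0.15,
) -> tuple[HaplotypeSet, GroundTruth]:
    """Forward Wright-Fisher simulation of the two-split demography with
    optional planted sweeps; returns sampled phased haplotypes plus ground
    truth.

    Sweep conditioning: ``complete`` sweeps must be fixed in the target
    population at sampling and ``partial`` sweeps must segregate within
    ``freq_tolerance`` of their target frequency; failing runs are
    rejection-resampled with fresh seeds up to ``rejection_cap`` attempts.
    """
    if region_length < 1000:
        raise ValueError("region_length must be >= 1 kb")
    for n in (model.N_anc, model.N_bottleneck1, model.N_bottleneck2, model.N_breed):
        if n > 2000:
            raise ValueError(
                "forward mode is desk-scale: rescale sizes to <= 2000 diploids"
            )
    if model.T_split < 1 or model.T_dom < 1:
        raise ValueError("forward mode needs T_dom >= T_split >= 1")
    for sw in sweeps:
        if not 0 <= sw.position < region_length:
            raise ValueError("sweep position outside the simulated region")
        if sw.target_population not in labels[:2]:
            raise ValueError("sweep target must be one of the two breeds")
        if sw.onset_generation >= model.T_split:
            raise ValueError(
                "sweep onset precedes the target breed's existence"
            )
    tr_sweeps: list[dict] = []
    ss_master = np.random.SeedSequence(seed)
    n_rejections = 0
    for attempt, child in enumerate(ss_master.spawn(max(1, rejection_cap))):
        rng = np.random.default_rng(child)
        state, tr_sweeps, events = _forward_attempt(
            model, sweeps, region_length, rng, labels
        )
        for tr, sw in zip(tr_sweeps, sweeps):
            tr["target_frequency"] = sw.target_frequency
        if not sweeps or _sweep_accepted(tr_sweeps, freq_tolerance):
            break
        n_rejections += 1
    else:
        raise RuntimeError(
            f"sweep conditioning failed after {rejection_cap} attempts"
        )

    # sample diploids per population
    rows = []
    pop_labels = []
    for lbl in labels:
        n = samples_per_pop.get(lbl, 0)
        mat = state.pops[lbl]
        n_avail = mat.shape[0] // 2
        if n > n_avail:
            raise ValueError(
                f"requested {n} diploids from {lbl!r} but only {n_avail} exist"
            )
        picked = np.sort(rng.choice(n_avail, size=n, replace=False))
        for i in picked:
            rows.append(mat[2 * i])
            rows.append(mat[2 * i + 1])
            pop_labels.extend([lbl, lbl])
    sample = np.vstack(rows)
    counts = sample.sum(axis=0, dtype=np.int64)
    seg = (counts > 0) & (counts < sample.shape[0])
    order = np.argsort(state.positions[seg], kind="mergesort")
    alleles = sample[:, seg][:, order]
    positions = state.positions[seg][order]
    haps = HaplotypeSet(
        alleles=alleles,
        chrom=np.full(positions.size, "1"),
        positions=positions,
        populations=np.array(pop_labels),
    )
    truth = GroundTruth(
        seed=seed, n_rejections=n_rejections, sweeps=tr_sweeps, events=events
    )
    return haps, truth


# ---------------------------------------------------------------------------
# Toy annotation tracks
# ---------------------------------------------------------------------------

_SUBCATEGORIES = {
    "production": ["growth_rate", "feed_intake", "backfat"],
    "reproduction": ["litter_size", "born_alive", "teat_number"],
    "exterior": ["coat_color", "ear_shape", "leg_conformation"],
    "health": ["immune_response", "disease_resistance", "parasite_load"],
}


def make_toy_annotations(
    region_length: int,
    n_genes: int,
    n_qtl: int,
    seed: int,
    chrom: str = "1",
) -> tuple[list[GeneModel], list[QtlInterval]]:
    """Non-overlapping gene spans plus random QTL intervals carrying the
    four-way category labels; deterministic under a fixed seed."""
    if n_genes < 1:
        raise ValueError("need at least one gene")
    rng = np.random.default_rng(seed)
    gene_len = max(100, region_length // (4 * n_genes))
    total_gap = region_length - n_genes * gene_len
    if total_gap < 0:
        raise ValueError("genes cannot fit in the region without overlap")
    gaps = rng.multinomial(total_gap, np.full(n_genes + 1, 1.0 / (n_genes + 1)))
    genes: list[GeneModel] = []
    cursor = 0
    for i in range(n_genes):
        cursor += int(gaps[i])
        genes.append(
            GeneModel(
                gene_id=f"gene{i + 1:04d}",
                chrom=chrom,
                start=cursor,
                stop=cursor + gene_len,
                strand="+" if rng.random() < 0.5 else "-",
            )
        )
        cursor += gene_len
    qtls: list[QtlInterval] = []
    for i in range(n_qtl):
        length = int(rng.integers(region_length // 50 + 1, max(region_length // 10, region_length // 50 + 2)))
        start = int(rng.integers(0, max(1, region_length - length)))
        category = QTL_CATEGORIES[i % len(QTL_CATEGORIES)]
        sub = _SUBCATEGORIES[category][int(rng.integers(len(_SUBCATEGORIES[category])))]
        qtls.append(
            QtlInterval(
                chrom=chrom,
                start=start,
                stop=start + length,
                category=category,
                subcategory=sub,
                size_cm=length / 1e6,
            )
        )
    return genes, qtls
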