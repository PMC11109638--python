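"""Forward-in-time genome-evolution simulator.

Evolves one ancestral genome along a user-specified schedule of dated events
(speciations, whole-genome duplications/triplications with fractionation,
chromosome fusions, fissions and inversions) and returns the extant genomes
together with a ground-truth record: the realised events, each extant gene's
ancestral gene and chromosome, and the expected synonymous divergence
Ks = 2·r·T for every homologous pair (T = time since the pair's most recent
divergence event, r = synonymous substitution rate per site per year).

Two modes are provided. Sequence mode evolves codon sequences explicitly:
along every branch each gene receives Poisson(r · branch_years · S) accepted
synonymous substitutions, where S is its Nei–Gojobori synonymous-site count;
substitution targets are proposed uniformly over positions and rejected
(and redrawn) while they would be nonsynonymous — with probability 1 − omega —
or would create a stop codon. Repeated hits at one site are allowed, so the
downstream Jukes–Cantor-corrected estimate converges to 2·r·T. Fast mode
("ks_level") skips sequences and emits, for every homologous pair, the noisy
observation true_ks × LogNormal(0, ks_scatter_sigma).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .codons import CODONS, IS_STOP, SYN_SITES_BY_INDEX

EVENT_KINDS = frozenset({"wgd", "triplication", "speciation", "fusion", "fission", "inversion"})

YEARS_PER_MY = 1e6


class SimulationConfigError(ValueError):
    """Raised when a simulation configuration or schedule is invalid."""


class SimulationInternalError(RuntimeError):
    """Raised on states the simulator must prevent by construction."""


@dataclass
class TimedEvent:
    """A dated evolutionary event applied to one lineage.

    ``time`` is in MYA (million years ago); ``params`` carries the
    event-specific fields: ``children`` for a speciation, ``chrom_a``/
    ``chrom_b`` for a fusion, ``chromosome``/``at_rank`` for a fission,
    ``chromosome``/``start``/``end`` for an inversion, optional ``loss``
    override for a WGD or triplication.
    """

    time: float
    lineage: str
    kind: str
    params: dict = field(default_factory=dict)


@dataclass
class SimConfig:
    n_chromosomes: int = 7
    genes_per_chromosome: int = 100
    codons_per_gene: int = 300
    rate_r: float = 4.29e-9  # synonymous substitutions / site / year
    omega: float = 0.0  # fraction of nonsynonymous proposals accepted
    schedule: list[TimedEvent] = field(default_factory=list)
    ks_scatter_sigma: float = 0.15  # lognormal sd of fast-mode Ks noise
    fractionation_loss: float = 0.2  # per-copy loss probability after WGD
    seed: int = 0
    mode: str = "sequence"  # "sequence" | "ks_level"
    root_lineage: str = "anc"

    def validate(self) -> None:
        if self.rate_r <= 0:
            raise SimulationConfigError("rate_r must be positive")
        if not (0 <= self.fractionation_loss < 1):
            raise SimulationConfigError("fractionation_loss must be in [0, 1)")
        if not (0 <= self.omega <= 1):
            raise SimulationConfigError("omega must be in [0, 1]")
        if self.codons_per_gene < 50:
            raise SimulationConfigError("codons_per_gene must be >= 50")
        if self.mode not in ("sequence", "ks_level"):
            raise SimulationConfigError(f"unknown mode {self.mode!r}")
        times = [e.time for e in self.schedule]
        if any(t2 >= t1 for t1, t2 in zip(times, times[1:])):
            raise SimulationConfigError("schedule times must be strictly decreasing (MYA)")
        if any(t <= 0 for t in times):
            raise SimulationConfigError("event times must be > 0 MYA")
        for ev in self.schedule:
            if ev.kind not in EVENT_KINDS:
                raise SimulationConfigError(f"unknown event kind {ev.kind!r}")


@dataclass
class TruthLog:
    """Ground truth of one simulation run.

    ``gene_genealogy`` maps every extant gene id to its ancestral gene
    (family) id and ancestral chromosome; ``true_pair_ks`` maps every
    homologous extant pair (canonically ordered id tuple) to its expected
    Ks = 2·r·T; ``fast_ks`` holds the noisy fast-mode observations (empty in
    sequence mode).
    """

    events: list[TimedEvent]
    gene_genealogy: dict[str, tuple[str, str]]
    true_pair_ks: dict[tuple[str, str], float]
    fast_ks: dict[tuple[str, str], float]
    species: list[str]
    seed: int


def expected_ks(rate_r: float, time_mya: float) -> float:
    """Expected synonymous divergence of a pair separated ``time_mya`` ago.

    E[Ks] = 2 · r · T with T in years (two branches of length T each
    accumulating r substitutions per synonymous site per year).
    """
    if rate_r < 0 or time_mya < 0:
        raise ValueError("rate and time must be nonnegative")
    if rate_r == 0:
        raise ValueError("rate_r must be positive")
    return 2.0 * rate_r * time_mya * YEARS_PER_MY


def sample_ks_values(
    rate_r: float, time_mya: float, n: int, sigma: float, rng: np.random.Generator
) -> np.ndarray:
    """Fast-mode Ks sample for one divergence event: 2·r·T × LogNormal(0, sigma)."""
    base = expected_ks(rate_r, time_mya)
    return base * np.exp(rng.normal(0.0, sigma, size=n))


# ---------------------------------------------------------------------------
# internal state


# per codon index: 9 single-nucleotide variants as (new_codon_index, kind)
# kind: 0 = synonymous, 1 = nonsynonymous, 2 = stop-creating (never accepted)
_ALL_CHANGES: list[list[tuple[int, int]]] = []


def _build_change_table() -> None:
    from .codons import GENETIC_CODE, BASES

    for ci, codon in enumerate(CODONS):
        entries: list[tuple[int, int]] = []
        if not IS_STOP[ci]:
            for pos in range(3):
                for b in BASES:
                    if b == codon[pos]:
                        continue
                    var = codon[:pos] + b + codon[pos + 1 :]
                    vi = CODONS.index(var)
                    if IS_STOP[vi]:
                        entries.append((vi, 2))
                    elif GENETIC_CODE[var] == GENETIC_CODE[codon]:
                        entries.append((vi, 0))
                    else:
                        entries.append((vi, 1))
        _ALL_CHANGES.append(entries)


_build_change_table()

_SENSE_CODON_INDICES = np.array([i for i in range(64) if not IS_STOP[i]])
_SYN_SITES_ARR = np.array(SYN_SITES_BY_INDEX)


class _Copy:
    """One gene copy inside the evolving state."""

    __slots__ = ("node", "family", "anc_chrom", "strand", "seq")

    def __init__(self, node, family, anc_chrom, strand="+", seq=None):
        self.node = node
        self.family = family
        self.anc_chrom = anc_chrom
        self.strand = strand
        self.seq = seq


class _Genealogy:
    """Gene-copy genealogy: parent pointers plus the time each node split."""

    def __init__(self):
        self.parent: list[int] = []
        self.split_time: dict[int, float] = {}

    def new_root(self) -> int:
        self.parent.append(-1)
        return len(self.parent) - 1

    def split(self, node: int, time_mya: float, n_children: int) -> list[int]:
        self.split_time[node] = time_mya
        children = []
        for _ in range(n_children):
            self.parent.append(node)
            children.append(len(self.parent) - 1)
        return children

    def divergence_time(self, u: int, v: int) -> float:
        """Time (MYA) at which the lineages of nodes u and v split."""
        anc = {}
        x = u
        while x != -1:
            anc[x] = True
            x = self.parent[x]
        x = v
        while x != -1:
            if x in anc:
                return self.split_time[x]
            x = self.parent[x]
        raise SimulationInternalError("nodes share a family but no common ancestor")


def _lineage_rng(seed: int, lineage: str, salt: int = 0) -> np.random.Generator:
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(lineage.encode()), salt])


def _mutate_gene(seq: np.ndarray, n_subs: int, omega: float, rng: np.random.Generator) -> None:
    """Apply ``n_subs`` accepted substitutions in place (rejection sampling)."""
    L = len(seq)
    for _ in range(n_subs):
        while True:
            j = int(rng.integers(L))
            k = int(rng.integers(9))
            vi, kind = _ALL_CHANGES[seq[j]][k]
            if kind == 2:
                continue  # stop codons are prevented by construction
            if kind == 1 and (omega == 0.0 or rng.random() >= omega):
                continue
            seq[j] = vi
            break


def _mutate_lineage(
    chroms, dt_mya: float, cfg: SimConfig, rng: np.random.Generator
) -> None:
    if dt_mya <= 0 or cfg.mode != "sequence":
        return
    years = dt_mya * YEARS_PER_MY
    for _name, copies in chroms:
        for cp in copies:
            s_sites = float(_SYN_SITES_ARR[cp.seq].sum())
            n = int(rng.poisson(cfg.rate_r * years * s_sites))
            if n:
                _mutate_gene(cp.seq, n, cfg.omega, rng)


def _resolve_chrom(chroms, ref, what: str) -> int:
    if isinstance(ref, int):
        if not (0 <= ref < len(chroms)):
            raise SimulationConfigError(f"{what}: chromosome index {ref} out of range")
        return ref
    for i, (name, _c) in enumerate(chroms):
        if name == ref:
            return i
    raise SimulationConfigError(f"{what}: no chromosome named {ref!r}")


def _renumber(chroms) -> None:
    for i, entry in enumerate(chroms):
        entry[0] = f"chr{i + 1:02d}"


def simulate_evolution(config: SimConfig):
    """Run the simulator; returns ({species: Genome}, TruthLog).

    Deterministic for a fixed seed: every lineage draws from its own RNG
    stream derived from (seed, lineage name), so adding a lineage to the
    schedule does not perturb the others.
    """
    from .genome import Gene, Genome

    config.validate()
    gen = _Genealogy()

    # --- found the root genome
    root_rng = _lineage_rng(config.seed, config.root_lineage, salt=1)
    lineages: dict[str, list] = {config.root_lineage: []}
    n_fam = 0
    for ci in range(config.n_chromosomes):
        anc_chrom = f"A{ci + 1:02d}"
        copies = []
        for _ in range(config.genes_per_chromosome):
            node = gen.new_root()
            fam = f"fam{n_fam:05d}"
            n_fam += 1
            seq = None
            if config.mode == "sequence":
                seq = root_rng.choice(
                    _SENSE_CODON_INDICES, size=config.codons_per_gene
                ).astype(np.int64)
            copies.append(_Copy(node, fam, anc_chrom, "+", seq))
        lineages[config.root_lineage].append([f"chr{ci + 1:02d}", copies])

    mut_rngs = {config.root_lineage: _lineage_rng(config.seed, config.root_lineage, salt=2)}
    evt_rngs = {config.root_lineage: _lineage_rng(config.seed, config.root_lineage, salt=3)}

    def _ensure_lineage_rngs(name: str) -> None:
        mut_rngs[name] = _lineage_rng(config.seed, name, salt=2)
        evt_rngs[name] = _lineage_rng(config.seed, name, salt=3)

    realized: list[TimedEvent] = []
    t_now = config.schedule[0].time if config.schedule else 0.0

    for ev in config.schedule:
        # evolve all lineages down to the event time
        for lin, chroms in lineages.items():
            _mutate_lineage(chroms, t_now - ev.time, config, mut_rngs[lin])
        t_now = ev.time

        if ev.lineage not in lineages:
            raise SimulationConfigError(
                f"event at {ev.time} MYA targets unknown lineage {ev.lineage!r}"
            )
        chroms = lineages[ev.lineage]

        if ev.kind == "speciation":
            children = ev.params.get("children") or [f"{ev.lineage}A", f"{ev.lineage}B"]
            if len(children) != 2 or children[0] == children[1]:
                raise SimulationConfigError("speciation needs two distinct child names")
            if any(c in lineages for c in children):
                raise SimulationConfigError("speciation child name already in use")
            state_a, state_b = [], []
            for name, copies in chroms:
                ca, cb = [], []
                for cp in copies:
                    na, nb = gen.split(cp.node, ev.time, 2)
                    seq_a = cp.seq.copy() if cp.seq is not None else None
                    seq_b = cp.seq.copy() if cp.seq is not None else None
                    ca.append(_Copy(na, cp.family, cp.anc_chrom, cp.strand, seq_a))
                    cb.append(_Copy(nb, cp.family, cp.anc_chrom, cp.strand, seq_b))
                state_a.append([name, ca])
                state_b.append([name, cb])
            del lineages[ev.lineage]
            lineages[children[0]] = state_a
            lineages[children[1]] = state_b
            _ensure_lineage_rngs(children[0])
            _ensure_lineage_rngs(children[1])

        elif ev.kind in ("wgd", "triplication"):
            n_copies = 2 if ev.kind == "wgd" else 3
            loss = float(ev.params.get("loss", config.fractionation_loss))
            if not (0 <= loss < 1):
                raise SimulationConfigError("fractionation loss must be in [0, 1)")
            rng = evt_rngs[ev.lineage]
            new_state = []
            dup_sets: list[list] = [[] for _ in range(n_copies)]
            for name, copies in chroms:
                per_copy: list[list] = [[] for _ in range(n_copies)]
                for cp in copies:
                    child_nodes = gen.split(cp.node, ev.time, n_copies)
                    for k, node in enumerate(child_nodes):
                        seq = cp.seq.copy() if cp.seq is not None else None
                        per_copy[k].append(_Copy(node, cp.family, cp.anc_chrom, cp.strand, seq))
                for k in range(n_copies):
                    dup_sets[k].append([name, per_copy[k]])
            for k in range(n_copies):
                new_state.extend(dup_sets[k])
            # fractionation: every post-duplication copy lost independently
            if loss > 0:
                for entry in new_state:
                    entry[1] = [cp for cp in entry[1] if rng.random() >= loss]
            new_state = [e for e in new_state if e[1]]
            _renumber(new_state)
            lineages[ev.lineage] = new_state

        elif ev.kind == "fusion":
            ia = _resolve_chrom(chroms, ev.params.get("chrom_a"), "fusion")
            ib = _resolve_chrom(chroms, ev.params.get("chrom_b"), "fusion")
            if ia == ib:
                raise SimulationConfigError("fusion requires two distinct chromosomes")
            chroms[ia][1].extend(chroms[ib][1])  # head-to-tail, unflipped
            del chroms[ib]
            _renumber(chroms)

        elif ev.kind == "fission":
            ic = _resolve_chrom(chroms, ev.params.get("chromosome"), "fission")
            at = ev.params.get("at_rank")
            name, copies = chroms[ic]
            if not isinstance(at, int) or not (1 <= at < len(copies)):
                raise SimulationConfigError(
                    f"fission split point {at!r} invalid for {len(copies)}-gene chromosome"
                )
            chroms[ic] = [name, copies[:at]]
            chroms.append([name + "f", copies[at:]])
            _renumber(chroms)

        elif ev.kind == "inversion":
            ic = _resolve_chrom(chroms, ev.params.get("chromosome"), "inversion")
            name, copies = chroms[ic]
            a = int(ev.params.get("start", 0))
            b = int(ev.params.get("end", len(copies) - 1))
            if not (0 <= a <= b < len(copies)):
                raise SimulationConfigError("inversion interval out of range")
            seg = copies[a : b + 1][::-1]
            for cp in seg:
                cp.strand = "-" if cp.strand == "+" else "+"
            chroms[ic][1] = copies[:a] + seg + copies[b + 1 :]

        realized.append(TimedEvent(ev.time, ev.lineage, ev.kind, dict(ev.params)))

    # evolve every lineage from the last event to the present
    for lin, chroms in lineages.items():
        _mutate_lineage(chroms, t_now - 0.0, config, mut_rngs[lin])

    # --- finalise extant genomes
    genomes: dict[str, Genome] = {}
    copy_by_gene_id: dict[str, _Copy] = {}
    for lin in sorted(lineages):
        chrom_dict: dict[str, list[Gene]] = {}
        counter = 0
        for name, copies in lineages[lin]:
            genes = []
            for rank, cp in enumerate(copies):
                gid = f"{lin}_g{counter:05d}"
                counter += 1
                cds = None
                if cp.seq is not None:
                    cds = "".join(CODONS[int(i)] for i in cp.seq)
                genes.append(
                    Gene(
                        id=gid,
                        chromosome=name,
                        order=rank,
                        start=rank * 10000,
                        end=rank * 10000 + 3 * config.codons_per_gene,
                        strand=cp.strand,
                        cds=cds,
                        family=cp.family,
                    )
                )
                copy_by_gene_id[gid] = cp
            chrom_dict[name] = genes
        genomes[lin] = Genome(species=lin, chromosomes=chrom_dict)

    # --- truth: genealogy and expected pair Ks
    genealogy_out: dict[str, tuple[str, str]] = {}
    by_family: dict[str, list[str]] = {}
    for lin in sorted(genomes):
        for g in genomes[lin].genes():
            cp = copy_by_gene_id[g.id]
            genealogy_out[g.id] = (cp.family, cp.anc_chrom)
            by_family.setdefault(cp.family, []).append(g.id)

    true_pair_ks: dict[tuple[str, str], float] = {}
    for fam in sorted(by_family):
        members = sorted(by_family[fam])
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                t = gen.divergence_time(copy_by_gene_id[a].node, copy_by_gene_id[b].node)
                true_pair_ks[(a, b)] = expected_ks(config.rate_r, t)

    fast_ks: dict[tuple[str, str], float] = {}
    if config.mode == "ks_level":
        noise_rng = _lineage_rng(config.seed, "__fast_ks__", salt=4)
        for pair in sorted(true_pair_ks):
            fast_ks[pair] = true_pair_ks[pair] * float(
                np.exp(noise_rng.normal(0.0, config.ks_scatter_sigma))
            )

    truth = TruthLog(
        events=realized,
        gene_genealogy=genealogy_out,
        true_pair_ks=true_pair_ks,
        fast_ks=fast_ks,
        species=sorted(genomes),
        seed=config.seed,
    )
    return genomes, truth


# ---------------------------------------------------------------------------
# I/O


def write_truth_json(truth: TruthLog, path) -> None:
    payload = {
        "seed": truth.seed,
        "species": truth.species,
        "events": [asdict(e) for e in truth.events],
        "gene_genealogy": {k: list(v) for k, v in truth.gene_genealogy.items()},
        "true_pair_ks": {f"{a}|{b}": ks for (a, b), ks in truth.true_pair_ks.items()},
        "fast_ks": {f"{a}|{b}": ks for (a, b), ks in truth.fast_ks.items()},
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth_json(path) -> TruthLog:
    with open(path) as fh:
        payload = json.load(fh)

    def _unpair(d):
        return {tuple(k.split("|")): v for k, v in d.items()}

    return TruthLog(
        events=[TimedEvent(**e) for e in payload["events"]],
        gene_genealogy={k: tuple(v) for k, v in payload["gene_genealogy"].items()},
        true_pair_ks=_unpair(payload["true_pair_ks"]),
        fast_ks=_unpair(payload["fast_ks"]),
        species=payload["species"],
        seed=payload["seed"],
    )


def write_config_yaml(config: SimConfig, path) -> None:
    d = asdict(config)
    d["schedule"] = [asdict(e) for e in config.schedule]
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)


def read_config_yaml(path) -> SimConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["schedule"] = [TimedEvent(**e) for e in d.get("schedule", [])]
    cfg = SimConfig(**d)
    cfg.validate()
    return cfg
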