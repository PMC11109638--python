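"""Pairwise synonymous divergence (Nei–Gojobori 1986) and Ks-distribution peaks.

Ks for a gene pair is estimated by NG86 counting: synonymous/nonsynonymous
sites per codon from the standard genetic code, differences averaged over
all mutational pathways, and the Jukes–Cantor multiple-hit correction
ks = −(3/4)·ln(1 − (4/3)·ps). Peaks of a Ks distribution — the signature of
whole-genome duplications — are located by fitting Gaussian mixtures to
ln(Ks) with a weighted EM algorithm, selecting the component count by BIC,
and bootstrap-resampling for confidence intervals. The reported peak of a
component is exp(mean_log), its median on the Ks scale.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from . import codons as _cd
from .genome import Genome
from .homology import HomologPair
from .simulate import TruthLog

MIN_ALIGNED_CODONS = 30
_SIGMA_FLOOR = 1e-3
_EM_MAX_ITER = 500


class StopCodonError(ValueError):
    """A coding sequence contains an internal stop codon."""


@dataclass
class KsEstimate:
    pair: tuple[str, str]
    aligned_codons: int = 0
    s_sites: float = 0.0
    n_sites: float = 0.0
    sd: float = 0.0
    nd: float = 0.0
    ps: float = float("nan")
    pn: float = float("nan")
    ks: float = float("nan")
    ka: float = float("nan")
    flag: str = "ok"  # ok | saturated | undefined


@dataclass
class KsDistribution:
    values: np.ndarray
    weights: np.ndarray
    source: str  # anchors | paranome | orthologs
    filter: tuple[float, float]

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class MixtureModel:
    k: int
    components: list[tuple[float, float, float]]  # (weight, mean_log, sd_log)
    bic: float
    loglik: float
    peaks: list[float]
    peak_ci: list[tuple[float, float]] | None = None
    converged: bool = True


# ---------------------------------------------------------------------------
# codon alignment


@dataclass
class AlignedCodonPair:
    codons_a: list[str]
    codons_b: list[str]
    n_dropped: int = 0


def _split_codons(cds: str, gene_id: str) -> list[str]:
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3:
        raise ValueError(f"CDS of {gene_id} has length {len(cds)}, not a multiple of 3")
    cod = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(cod[:-1]):
        if c in _cd.STOP_CODONS:
            raise StopCodonError(f"internal stop codon {c} at codon {i} of {gene_id}")
    if cod and cod[-1] in _cd.STOP_CODONS:
        cod = cod[:-1]  # trailing stop trimmed
    return cod


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1
_aligner.mismatch_score = -1
_aligner.open_gap_score = -2
_aligner.extend_gap_score = -2


def align_codon_pair(
    cds_a: str, cds_b: str, ids: tuple[str, str] = ("seq_a", "seq_b")
) -> AlignedCodonPair:
    """Codon-aware pairwise alignment.

    Equal-length sequences pass through unchanged; unequal lengths are
    aligned globally on their translations and back-translated, dropping
    gapped codon columns.
    """
    ca = _split_codons(cds_a, ids[0])
    cb = _split_codons(cds_b, ids[1])
    if len(ca) == len(cb):
        return AlignedCodonPair(ca, cb, 0)
    prot_a = "".join(_cd.GENETIC_CODE[c] for c in ca)
    prot_b = "".join(_cd.GENETIC_CODE[c] for c in cb)
    aln = _aligner.align(prot_a, prot_b)[0]
    out_a: list[str] = []
    out_b: list[str] = []
    n_dropped = 0
    for (sa, ea), (sb, eb) in zip(*aln.aligned):
        out_a.extend(ca[sa:ea])
        out_b.extend(cb[sb:eb])
    n_dropped = max(len(ca), len(cb)) - len(out_a)
    return AlignedCodonPair(out_a, out_b, n_dropped)


def ng86(aligned: AlignedCodonPair, pair: tuple[str, str] = ("seq_a", "seq_b")) -> KsEstimate:
    """Nei–Gojobori (1986) Ks/Ka with Jukes–Cantor correction."""
    ca, cb = aligned.codons_a, aligned.codons_b
    n_codons = len(ca)
    est = KsEstimate(pair=pair, aligned_codons=n_codons)
    if n_codons < MIN_ALIGNED_CODONS:
        est.flag = "undefined"
        return est
    s_a = sum(_cd.syn_sites(c) for c in ca)
    s_b = sum(_cd.syn_sites(c) for c in cb)
    est.s_sites = 0.5 * (s_a + s_b)
    est.n_sites = 3.0 * n_codons - est.s_sites
    sd = nd = 0.0
    for x, y in zip(ca, cb):
        dsd, dnd = _cd.pair_differences(x, y)
        sd += dsd
        nd += dnd
    est.sd, est.nd = sd, nd
    est.ps = sd / est.s_sites if est.s_sites > 0 else float("nan")
    est.pn = nd / est.n_sites if est.n_sites > 0 else float("nan")

    def _jc(p: float) -> float:
        return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)

    if not math.isfinite(est.ps):
        est.flag = "undefined"
    elif est.ps >= 0.75:
        est.flag = "saturated"
    else:
        est.ks = _jc(est.ps)
        est.ka = _jc(est.pn) if est.pn < 0.75 else float("nan")
    return est


def ks_for_pairs(
    genome_a: Genome, genome_b: Genome, pairs: list[HomologPair]
) -> list[KsEstimate]:
    """Sequence-mode Ks: align and estimate for every homolog pair."""
    out = []
    for p in pairs:
        ga = genome_a.get(p.gene_a) or genome_b.get(p.gene_a)
        gb = genome_b.get(p.gene_b) or genome_a.get(p.gene_b)
        if ga is None or gb is None or ga.cds is None or gb.cds is None:
            out.append(KsEstimate(pair=(p.gene_a, p.gene_b), flag="undefined"))
            continue
        aligned = align_codon_pair(ga.cds, gb.cds, (ga.id, gb.id))
        out.append(ng86(aligned, (ga.id, gb.id)))
    return out


def ks_from_truth(truth: TruthLog, pairs: list[HomologPair]) -> list[KsEstimate]:
    """Fast-mode Ks: read the simulator's noisy per-pair values."""
    source = truth.fast_ks if truth.fast_ks else truth.true_pair_ks
    out = []
    for p in pairs:
        key = (p.gene_a, p.gene_b) if p.gene_a <= p.gene_b else (p.gene_b, p.gene_a)
        if key not in source:
            raise KeyError(f"pair {key} not present in the truth log")
        out.append(KsEstimate(pair=key, ks=float(source[key]), flag="ok"))
    return out


def reciprocal_min_ks(estimates: list[KsEstimate]) -> list[KsEstimate]:
    """Keep reciprocal closest pairs: the ortholog analogue of best BLAST hits.

    Cross-species homolog lists contain, besides true orthologs, pairs split
    at WGDs predating the speciation; keeping for each gene only its
    minimum-Ks partner (reciprocally) isolates the ortholog signal used for
    rate calibration.
    """
    best: dict[str, KsEstimate] = {}
    for e in estimates:
        if e.flag != "ok" or not math.isfinite(e.ks):
            continue
        for g in e.pair:
            if g not in best or e.ks < best[g].ks:
                best[g] = e
    return [e for e in estimates if best.get(e.pair[0]) is e and best.get(e.pair[1]) is e]


# ---------------------------------------------------------------------------
# distributions


def build_distribution(
    estimates: list[KsEstimate],
    source: str,
    ks_min: float = 0.01,
    ks_max: float = 5.0,
) -> KsDistribution:
    """Filtered, weighted Ks distribution.

    Saturated/undefined estimates and values outside (ks_min, ks_max] are
    dropped. For the whole paranome, large gene families are down-weighted:
    each pair carries weight 1/(pairs contributed by its family), families
    being connected components of the pair graph. Anchor and ortholog pairs
    carry weight 1.
    """
    if source not in ("anchors", "paranome", "orthologs"):
        raise ValueError(f"unknown source {source!r}")
    kept = [
        e for e in estimates
        if e.flag == "ok" and math.isfinite(e.ks) and ks_min < e.ks <= ks_max
    ]
    if not kept:
        raise ValueError("no Ks estimates survive filtering")
    if source == "paranome":
        import networkx as nx

        G = nx.Graph()
        G.add_edges_from(e.pair for e in estimates if e.pair is not None)
        comp_of: dict[str, int] = {}
        comp_pairs: dict[int, int] = {}
        for ci, comp in enumerate(nx.connected_components(G)):
            for g in comp:
                comp_of[g] = ci
        for e in estimates:
            if e.pair is not None:
                ci = comp_of[e.pair[0]]
                comp_pairs[ci] = comp_pairs.get(ci, 0) + 1
        weights = np.array([1.0 / comp_pairs[comp_of[e.pair[0]]] for e in kept])
    else:
        weights = np.ones(len(kept))
    return KsDistribution(
        values=np.array([e.ks for e in kept]),
        weights=weights,
        source=source,
        filter=(ks_min, ks_max),
    )


# ---------------------------------------------------------------------------
# mixture modelling


def _em(x, w, mu, sigma, pi, tol):
    """Weighted EM for a 1-D Gaussian mixture; returns (loglik, mu, sigma, pi, converged)."""
    n, k = len(x), len(mu)
    prev = -np.inf
    converged = False
    w_sum = w.sum()
    for _ in range(_EM_MAX_ITER):
        log_pdf = (
            -0.5 * ((x[:, None] - mu[None, :]) / sigma[None, :]) ** 2
            - np.log(sigma[None, :])
            - 0.5 * math.log(2 * math.pi)
            + np.log(pi[None, :])
        )
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        loglik = float((w * lse).sum())
        resp = np.exp(log_pdf - lse[:, None])
        wr = resp * w[:, None]
        nk = wr.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        pi = nk / w_sum
        mu = (wr * x[:, None]).sum(axis=0) / nk
        var = (wr * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sigma = np.sqrt(np.maximum(var, _SIGMA_FLOOR**2))
        if abs(loglik - prev) < tol:
            converged = True
            break
        prev = loglik
    return loglik, mu, sigma, pi, converged


def _fit_at_k(x, w, k, n_restarts, tol, rng):
    best = None
    sd_all = max(float(np.sqrt(np.cov(x, aweights=w) if len(x) > 1 else 0.0)), _SIGMA_FLOOR)
    order = np.argsort(x)
    cum = np.cumsum(w[order]) / w.sum()
    for _ in range(n_restarts):
        qs = (np.arange(k) + 0.5) / k + rng.uniform(-0.3, 0.3, size=k) / k
        qs = np.clip(qs, 0.01, 0.99)
        mu = np.array([x[order[np.searchsorted(cum, q)]] for q in qs], dtype=float)
        sigma = np.full(k, max(sd_all / k, _SIGMA_FLOOR))
        pi = np.full(k, 1.0 / k)
        fit = _em(x, w, mu, sigma, pi, tol)
        if best is None or fit[0] > best[0]:
            best = fit
    return best


def fit_mixture(
    dist: KsDistribution,
    k_max: int = 5,
    n_restarts: int = 10,
    tol: float = 1e-6,
    seed: int | None = None,
    k: int | None = None,
) -> MixtureModel:
    """Fit Gaussian mixtures to ln(Ks) and select the component count by BIC.

    ``k`` fixes the component count (no selection); otherwise k = 1..k_max
    are fitted and the lowest-BIC model returned. Deterministic for a fixed
    seed. Needs at least 50 values.
    """
    if len(dist) < 50:
        raise ValueError(f"mixture fitting needs >= 50 Ks values, got {len(dist)}")
    x = np.log(dist.values)
    w = dist.weights.astype(float)
    rng = np.random.default_rng(seed)
    n_eff = float(w.sum())
    ks_to_try = [k] if k is not None else list(range(1, k_max + 1))
    best_model = None
    for kk in ks_to_try:
        loglik, mu, sigma, pi, converged = _fit_at_k(x, w, kk, n_restarts, tol, rng)
        if not converged:
            warnings.warn(f"EM did not converge for k={kk}; best-so-far returned", stacklevel=2)
        n_params = 3 * kk - 1
        bic = -2.0 * loglik + n_params * math.log(n_eff)
        order = np.argsort(mu)
        model = MixtureModel(
            k=kk,
            components=[(float(pi[i]), float(mu[i]), float(sigma[i])) for i in order],
            bic=float(bic),
            loglik=float(loglik),
            peaks=[float(np.exp(mu[i])) for i in order],
            converged=converged,
        )
        if best_model is None or model.bic < best_model.bic:
            best_model = model
    return best_model


def bootstrap_peaks(
    dist: KsDistribution,
    model_k: int,
    B: int = 200,
    seed: int | None = None,
    n_restarts: int = 3,
) -> list[tuple[float, float]]:
    """Percentile bootstrap (2.5/97.5) intervals for the sorted mixture peaks."""
    if B < 20:
        raise ValueError("bootstrap needs B >= 20 resamples")
    rng = np.random.default_rng(seed)
    n = len(dist)
    p = dist.weights / dist.weights.sum()
    peak_samples = np.empty((B, model_k))
    collapsed = 0
    for b in range(B):
        idx = rng.choice(n, size=n, replace=True, p=p)
        boot = KsDistribution(
            values=dist.values[idx],
            weights=np.ones(n),
            source=dist.source,
            filter=dist.filter,
        )
        model = fit_mixture(
            boot, n_restarts=n_restarts, seed=int(rng.integers(2**31)), k=model_k
        )
        mus = np.array([c[1] for c in model.components])
        sds = np.array([c[2] for c in model.components])
        if model_k > 1:
            gaps = np.diff(mus)  # components come sorted by mean
            widths = np.maximum(sds[:-1], sds[1:])
            # two Gaussians produce distinct modes only when separated by
            # roughly twice their width; closer neighbours are one peak
            if np.any(gaps < 2 * widths):
                collapsed += 1
        peak_samples[b] = model.peaks
    if collapsed > B / 2:
        warnings.warn(
            f"{collapsed}/{B} bootstrap refits collapsed components: "
            f"k={model_k} is likely more than the distribution supports",
            stacklevel=2,
        )
    lo = np.percentile(peak_samples, 2.5, axis=0)
    hi = np.percentile(peak_samples, 97.5, axis=0)
    return [(float(a), float(b)) for a, b in zip(lo, hi)]


# ---------------------------------------------------------------------------
# I/O


def write_ks_tsv(estimates: list[KsEstimate], path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("gene_a\tgene_b\taligned_codons\ts_sites\tn_sites\tks\tka\tflag\n")
        for e in estimates:
            fh.write(
                f"{e.pair[0]}\t{e.pair[1]}\t{e.aligned_codons}\t{e.s_sites:.4f}\t"
                f"{e.n_sites:.4f}\t{e.ks:.6f}\t{e.ka:.6f}\t{e.flag}\n"
            )


def write_histogram_tsv(dist: KsDistribution, path, bin_width: float = 0.05, meta: dict | None = None) -> None:
    lo, hi = dist.filter
    edges = np.arange(0.0, hi + bin_width, bin_width)
    counts, _ = np.histogram(dist.values, bins=edges, weights=dist.weights)
    with open(path, "w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("bin_start\tbin_end\tweight\n")
        for i, c in enumerate(counts):
            fh.write(f"{edges[i]:.3f}\t{edges[i + 1]:.3f}\t{c:.4f}\n")


def write_mixture_json(model: MixtureModel, path, meta: dict | None = None) -> None:
    payload = {
        "k": model.k,
        "components": [
            {"weight": w, "mean_log": m, "sd_log": s} for (w, m, s) in model.components
        ],
        "bic": model.bic,
        "loglik": model.loglik,
        "peaks": model.peaks,
        "peak_ci": model.peak_ci,
        "converged": model.converged,
    }
    if meta:
        payload["_meta"] = meta
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
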