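"""De novo discovery of clone-associated nuclear mutations.

Given clone assignments and per-cell allele counts at a user-supplied list
of candidate sites (e.g. recurrently mutated cancer positions), each site is
tested for clone-specific mutant allele frequencies. Per-cell alternative
read counts are modelled as beta-binomial draws; a null model with a single
mutant probability shared by all cells (H0: parameters mu and overdispersion
rho) is compared with an alternative with one mutant probability per clone
and a shared rho (H1) using Akaike's Information Criterion,
AIC = 2k - 2 logL. A positive delta_aic = AIC(H0) - AIC(H1) favours a
clone-specific mutant probability at that site.

Candidate sites are first filtered to expressed positions (mean reads per
cell above a threshold, default 20) and purged of known germline variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .counts import AlleleCountTable, GenomicSite

logger = logging.getLogger(__name__)

_EPS = 1e-6


@dataclass
class CandidateSiteList:
    """Candidate (site, alt, gene) triples for the association scan."""

    sites: list[tuple[GenomicSite, str, str]]
    source_note: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for site, alt, _ in self.sites:
            key = (site.contig, site.position, alt)
            if key in seen:
                raise ValueError(f"duplicate candidate entry {key}")
            seen.add(key)

    def __len__(self) -> int:
        return len(self.sites)

    @classmethod
    def from_tsv(cls, path: str | Path, source_note: str = "") -> "CandidateSiteList":
        df = pd.read_csv(path, sep="\t", dtype={"contig": str, "ref": str, "alt": str})
        sites = [
            (GenomicSite(r.contig, int(r.position), r.ref), r.alt,
             str(getattr(r, "gene", "")))
            for r in df.itertuples()
        ]
        return cls(sites, source_note or str(path))

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"contig": s.contig, "position": s.position, "ref": s.ref_allele,
             "alt": alt, "gene": gene}
            for s, alt, gene in self.sites
        ]
        pd.DataFrame(rows, columns=["contig", "position", "ref", "alt", "gene"]).to_csv(
            path, sep="\t", index=False
        )


@dataclass
class SiteAssociationResult:
    """Model comparison at one candidate site."""

    site: GenomicSite
    alt: str
    gene: str
    loglik_h0: float
    loglik_h1: float
    aic_h0: float
    aic_h1: float
    delta_aic: float
    mu_h0: float
    rho: float
    clone_mu: dict[str, float]
    n_cells_covered: int


def filter_candidate_sites(
    table: AlleleCountTable,
    raw_sites: CandidateSiteList,
    germline_exclusions: Iterable[tuple[str, int, str]] = (),
    min_mean_reads: float = 20.0,
) -> CandidateSiteList:
    """Keep expressed, non-germline candidates.

    Mean coverage per cell (cells without a record count as zero) must be
    strictly above ``min_mean_reads``; entries present in
    ``germline_exclusions`` — (contig, position, alt) triples — are removed.
    """
    excl = set(germline_exclusions)
    n = table.n_cells
    cov = table.df.assign(coverage=table.coverage)
    total = cov.groupby(["contig", "position"])["coverage"].sum()
    kept = []
    for site, alt, gene in raw_sites.sites:
        if (site.contig, site.position, alt) in excl:
            continue
        mean_cov = float(total.get((site.contig, site.position), 0)) / max(n, 1)
        if mean_cov > min_mean_reads:
            kept.append((site, alt, gene))
    return CandidateSiteList(kept, raw_sites.source_note)


def betabinom_loglik(
    alt_counts: Sequence[int],
    coverages: Sequence[int],
    mu: float,
    rho: float,
) -> float:
    """Beta-binomial log-likelihood of per-cell alternative read counts.

    The beta-binomial has mean probability ``mu`` and overdispersion ``rho``,
    i.e. shape parameters a = mu(1-rho)/rho, b = (1-mu)(1-rho)/rho; rho -> 0
    recovers the binomial. Cells with zero coverage are excluded.
    """
    if not 0 < mu < 1:
        raise ValueError(f"invalid mean: mu={mu} not in (0, 1)")
    if not 0 <= rho < 1:
        raise ValueError(f"invalid overdispersion: rho={rho} not in [0, 1)")
    k = np.asarray(alt_counts, dtype=np.int64)
    n = np.asarray(coverages, dtype=np.int64)
    if np.any(k > n):
        raise ValueError("alt count exceeds coverage")
    mask = n > 0
    k, n = k[mask], n[mask]
    if rho == 0:
        return float(stats.binom.logpmf(k, n, mu).sum())
    a = mu * (1 - rho) / rho
    b = (1 - mu) * (1 - rho) / rho
    return float(stats.betabinom.logpmf(k, n, a, b).sum())


def _neg_loglik_grouped(params, groups, shared_rho=True):
    """Negative log-likelihood; params = per-group mu values + one rho."""
    mus = params[:-1]
    rho = params[-1]
    total = 0.0
    for (k, n), mu in zip(groups, mus):
        total += betabinom_loglik(k, n, float(mu), float(rho))
    return -total


_MU_STARTS = (0.01, 0.1, 0.5)
_RHO_STARTS = (0.01, 0.1)


def _fit_grouped(groups, extra_starts=()):
    """Bounded ML fit of per-group mu with shared rho, multistart L-BFGS-B.

    ``groups`` is a list of (alt_counts, coverages) arrays. Returns
    (loglik, mus, rho). Deterministic: fixed start grid plus the empirical
    means, ties resolved by start order.
    """
    n_g = len(groups)
    emp = []
    for k, n in groups:
        tot = n.sum()
        emp.append(float(np.clip(k.sum() / tot if tot > 0 else 0.01, _EPS, 1 - _EPS)))
    starts = []
    for mu0 in _MU_STARTS:
        for rho0 in _RHO_STARTS:
            starts.append([mu0] * n_g + [rho0])
    for rho0 in _RHO_STARTS:
        starts.append(emp + [rho0])
    starts.extend(list(s) for s in extra_starts)
    bounds = [(_EPS, 1 - _EPS)] * n_g + [(_EPS, 0.95)]
    best = None
    for x0 in starts:
        x0 = np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = optimize.minimize(
            _neg_loglik_grouped, x0, args=(groups,), method="L-BFGS-B", bounds=bounds,
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    mus = [float(m) for m in best.x[:-1]]
    return -float(best.fun), mus, float(best.x[-1])


def scan_site(
    alt_counts: Sequence[int],
    coverages: Sequence[int],
    clone_of_cell: Sequence[str],
    site: GenomicSite | None = None,
    alt: str = "",
    gene: str = "",
) -> SiteAssociationResult:
    """Compare shared-mu (H0) against per-clone-mu (H1) beta-binomial fits.

    H0 has k = 2 free parameters (mu, rho); H1 has k = |C| + 1 (one mu per
    clone, shared rho). ``delta_aic = aic_h0 - aic_h1 > 0`` favours H1.
    Requires at least two clones each with at least one covered cell.
    """
    k = np.asarray(alt_counts, dtype=np.int64)
    n = np.asarray(coverages, dtype=np.int64)
    clones = np.asarray(clone_of_cell)
    if not (len(k) == len(n) == len(clones)):
        raise ValueError("alt counts, coverages and clone labels must align")
    covered = n > 0
    if not covered.any():
        raise ValueError("site not testable: all cells have zero coverage")
    k, n, clones = k[covered], n[covered], clones[covered]
    labels = sorted(set(clones))
    if len(labels) < 2:
        raise ValueError(">=2 clones required: only %r covered" % labels)

    ll0, (mu0,), rho0 = _fit_grouped([(k, n)])
    groups = [(k[clones == c], n[clones == c]) for c in labels]
    # include the H0 optimum as an H1 start so nesting holds numerically
    ll1, mus1, rho1 = _fit_grouped(groups, extra_starts=[[mu0] * len(labels) + [rho0]])
    ll1 = max(ll1, ll0)
    aic0 = 2 * 2 - 2 * ll0
    aic1 = 2 * (len(labels) + 1) - 2 * ll1
    return SiteAssociationResult(
        site=site if site is not None else GenomicSite("NA", 1, "A"),
        alt=alt,
        gene=gene,
        loglik_h0=ll0,
        loglik_h1=ll1,
        aic_h0=aic0,
        aic_h1=aic1,
        delta_aic=aic0 - aic1,
        mu_h0=mu0,
        rho=rho1,
        clone_mu=dict(zip(labels, mus1)),
        n_cells_covered=int(len(k)),
    )


def scan_sites(
    table: AlleleCountTable,
    candidates: CandidateSiteList,
    clone_of_cell: Mapping[str, str],
    assigned_cells: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Run :func:`scan_site` over a candidate list, ordered by delta_aic.

    Only confidently assigned cells should be passed (the 0.8 posterior
    filter); sites failing preconditions are skipped with a log message.
    """
    cells = sorted(assigned_cells) if assigned_cells is not None else sorted(clone_of_cell)
    rows = []
    for site, alt, gene in candidates.sites:
        counts = table.site_counts(site).reindex(cells).fillna(0).astype(np.int64)
        cov = counts.sum(axis=1).to_numpy()
        altr = counts[alt].to_numpy()
        labels = [clone_of_cell[c] for c in cells]
        try:
            res = scan_site(altr, cov, labels, site=site, alt=alt, gene=gene)
        except ValueError as exc:
            logger.info("skipping %s: %s", site.label(alt), exc)
            continue
        rows.append(
            {
                "contig": site.contig,
                "position": site.position,
                "ref": site.ref_allele,
                "alt": alt,
                "gene": gene,
                "loglik_h0": res.loglik_h0,
                "loglik_h1": res.loglik_h1,
                "aic_h0": res.aic_h0,
                "aic_h1": res.aic_h1,
                "delta_aic": res.delta_aic,
                "mu_h0": res.mu_h0,
                "rho": res.rho,
                "n_cells_covered": res.n_cells_covered,
                **{f"mu_{c}": m for c, m in res.clone_mu.items()},
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("delta_aic", ascending=False).reset_index(drop=True)
    return df
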