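"""PCA-window local ancestry with HMM smoothing.

A re-implementation in the spirit of PCAdmix: the chromosome is cut into
fixed-size windows of consecutive SNPs; in each window the pooled reference
haplotypes are projected onto their leading principal components and each
donor panel is modelled as a Gaussian on the scores (per-panel mean, pooled
covariance). Target haplotypes are scored per window and smoothed along the
chromosome with a two-state HMM whose switch probability derives from the
expected ancestry-tract length (1 - exp(-g * r * gap) per window boundary for
an admixture event g generations ago). Windows where the two panels are
statistically indistinguishable are flagged low-information and contribute
flat emissions, keeping coordinates contiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import HaplotypeMatrix

__all__ = ["AncestryModel", "AncestryTracks", "train_reference",
           "assign_ancestry", "allele_donor_fraction", "hudson_fst"]


def hudson_fst(panel_a: HaplotypeMatrix, panel_b: HaplotypeMatrix) -> float:
    """Genome-wide Hudson Fst between two panels (ratio-of-averages form).

    Used to check that reference panels are divergent enough to train an
    informative window classifier.
    """
    p1, p2 = panel_a.frequencies(), panel_b.frequencies()
    n1, n2 = panel_a.n_haplotypes, panel_b.n_haplotypes
    num = ((p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1)
           - p2 * (1 - p2) / (n2 - 1))
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = np.isfinite(den) & (den > 0)
    if not ok.any():
        raise ValueError("no polymorphic sites shared by the panels")
    return float(num[ok].sum() / den[ok].sum())


@dataclass
class WindowModel:
    sites: np.ndarray          # column indices
    mean_geno: np.ndarray      # pooled centering vector
    basis: np.ndarray          # (n_sites_in_window, k) principal axes
    mu_a: np.ndarray
    mu_b: np.ndarray
    cov: np.ndarray            # pooled (k, k)
    cov_inv: np.ndarray
    logdet: float
    low_information: bool


@dataclass
class AncestryModel:
    window_size: int
    k: int
    windows: list[WindowModel]
    positions: np.ndarray      # all SNP positions the model was trained on
    switch_base: float         # per-boundary switch probability (may be overridden)
    labels: tuple[str, str] = ("A", "B")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def low_information_fraction(self) -> float:
        return float(np.mean([w.low_information for w in self.windows]))

    def window_starts(self) -> np.ndarray:
        return np.array([w.sites[0] for w in self.windows])

    def window_of_site(self, site_index: int) -> int:
        for wi, w in enumerate(self.windows):
            if w.sites[0] <= site_index <= w.sites[-1]:
                return wi
        raise ValueError("site is not covered by any trained window")


def train_reference(panel_a: HaplotypeMatrix, panel_b: HaplotypeMatrix,
                    w: int = 20, k: int = 4, *, generations: float = 100.0,
                    r: float = 1e-8, min_sep_sd: float = 0.1) -> AncestryModel:
    """Fit per-window PCA projections and Gaussian class models.

    Windows where the class means are closer than ``min_sep_sd`` pooled
    standard deviations (along the mean-difference direction) are flagged
    low-information. Each panel needs at least 8 haplotypes.
    """
    if w < 5:
        raise ValueError("window size must be >= 5 SNPs")
    if k < 1:
        raise ValueError("need k >= 1 components")
    if not np.array_equal(panel_a.positions, panel_b.positions):
        raise ValueError("panels must share sites")
    if panel_a.n_haplotypes < 8 or panel_b.n_haplotypes < 8:
        raise ValueError("each reference panel needs >= 8 haplotypes")
    n_sites = panel_a.n_sites
    n_win = n_sites // w
    if n_win == 0:
        raise ValueError("fewer sites than one window")
    na, nb = panel_a.n_haplotypes, panel_b.n_haplotypes
    windows: list[WindowModel] = []
    for wi in range(n_win):
        sites = np.arange(wi * w, n_sites if wi == n_win - 1 else (wi + 1) * w)
        X = np.vstack([panel_a.H[:, sites], panel_b.H[:, sites]]).astype(float)
        center = X.mean(axis=0)
        Xc = X - center
        _, _, vt = np.linalg.svd(Xc, full_matrices=False)
        basis = vt[:k].T
        scores = Xc @ basis
        sa, sb = scores[:na], scores[na:]
        mu_a, mu_b = sa.mean(axis=0), sb.mean(axis=0)
        cov = (np.cov(sa.T, ddof=1) * (na - 1) + np.cov(sb.T, ddof=1) * (nb - 1))
        cov = np.atleast_2d(cov) / (na + nb - 2)
        cov += np.eye(k) * 1e-6 * max(np.trace(cov) / k, 1e-12)
        d = mu_a - mu_b
        dn = np.linalg.norm(d)
        sd_along = np.sqrt(d @ cov @ d) / dn if dn > 0 else np.inf
        # indistinguishable if closer than the stated floor OR within the
        # sampling noise of the class means (chi^2 null on the Mahalanobis
        # separation)
        cov_inv = np.linalg.inv(cov)
        m2 = float(d @ cov_inv @ d)
        noise2 = stats.chi2(k).ppf(0.95) * (1.0 / na + 1.0 / nb)
        low = (dn < min_sep_sd * sd_along) or (m2 < noise2)
        logdet = float(np.linalg.slogdet(cov)[1])
        windows.append(WindowModel(sites, center, basis, mu_a, mu_b, cov,
                                   cov_inv, logdet, bool(low)))
    # switch probability from mean inter-window distance
    starts = [panel_a.positions[win.sites[0]] for win in windows]
    gaps = np.diff(starts) if len(starts) > 1 else np.array([w * 1000.0])
    switch = float(1.0 - np.exp(-generations * r * np.mean(gaps)))
    switch = min(max(switch, 1e-6), 0.49)
    return AncestryModel(window_size=w, k=k, windows=windows,
                         positions=panel_a.positions.copy(), switch_base=switch)


@dataclass
class AncestryTracks:
    model: AncestryModel
    posterior_a: np.ndarray    # (n_haplotypes, n_windows)
    viterbi: np.ndarray        # (n_haplotypes, n_windows) 0=A, 1=B
    sample_ids: list[str]

    @property
    def q_hat(self) -> np.ndarray:
        """Posterior-weighted donor-A genome fraction per haplotype."""
        return self.posterior_a.mean(axis=1)

    def q_hat_individual(self) -> np.ndarray:
        q = self.q_hat
        return 0.5 * (q[0::2] + q[1::2])


def _emission_loglik(model: AncestryModel, H: np.ndarray) -> np.ndarray:
    """(n_hap, n_windows, 2) Gaussian log-likelihood of each donor."""
    n_hap = H.shape[0]
    ll = np.zeros((n_hap, model.n_windows, 2))
    for wi, wm in enumerate(model.windows):
        if wm.low_information:
            continue  # flat emissions
        scores = (H[:, wm.sites].astype(float) - wm.mean_geno) @ wm.basis
        for ci, mu in enumerate((wm.mu_a, wm.mu_b)):
            dev = scores - mu
            m = np.einsum("ij,jk,ik->i", dev, wm.cov_inv, dev)
            ll[:, wi, ci] = -0.5 * (m + wm.logdet)
    return ll


def _forward_backward(ll: np.ndarray, switch: float):
    """Scaled forward-backward + Viterbi for a 2-state chain, flat prior."""
    n_win = ll.shape[0]
    logtrans = np.log(np.array([[1 - switch, switch], [switch, 1 - switch]]))
    # forward-backward in probability space with scaling
    e = np.exp(ll - ll.max(axis=1, keepdims=True))
    trans = np.exp(logtrans)
    alpha = np.empty((n_win, 2))
    beta = np.empty((n_win, 2))
    alpha[0] = 0.5 * e[0]
    alpha[0] /= alpha[0].sum()
    for t in range(1, n_win):
        a = (alpha[t - 1] @ trans) * e[t]
        alpha[t] = a / a.sum()
    beta[-1] = 1.0
    for t in range(n_win - 2, -1, -1):
        b = trans @ (e[t + 1] * beta[t + 1])
        beta[t] = b / b.sum()
    post = alpha * beta
    post /= post.sum(axis=1, keepdims=True)
    # Viterbi
    delta = np.empty((n_win, 2))
    psi = np.zeros((n_win, 2), dtype=np.int64)
    delta[0] = np.log(0.5) + ll[0]
    for t in range(1, n_win):
        cand = delta[t - 1][:, None] + logtrans
        psi[t] = cand.argmax(axis=0)
        delta[t] = cand.max(axis=0) + ll[t]
    path = np.empty(n_win, dtype=np.int64)
    path[-1] = int(delta[-1].argmax())
    for t in range(n_win - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return post, path


def assign_ancestry(model: AncestryModel, targets: HaplotypeMatrix,
                    switch: float | None = None) -> AncestryTracks:
    """Donor posteriors and Viterbi labels per target haplotype per window."""
    if targets.n_sites != len(model.positions) or not np.array_equal(
            targets.positions, model.positions):
        raise ValueError("target sites do not match the trained model")
    sw = model.switch_base if switch is None else switch
    if not 0 < sw < 1:
        raise ValueError("switch probability must lie in (0, 1)")
    ll = _emission_loglik(model, targets.H)
    n_hap = targets.n_haplotypes
    post_a = np.empty((n_hap, model.n_windows))
    vit = np.empty((n_hap, model.n_windows), dtype=np.int64)
    for h in range(n_hap):
        post, path = _forward_backward(ll[h], sw)
        post_a[h] = post[:, 0]
        vit[h] = path
    return AncestryTracks(model=model, posterior_a=post_a, viterbi=vit,
                          sample_ids=list(targets.sample_ids))


def allele_donor_fraction(tracks: AncestryTracks, targets: HaplotypeMatrix,
                          focal_site: int, allele: int) -> dict[str, float]:
    """Among carriers of ``allele`` at ``focal_site``, the donor-A fraction.

    Reports both the Viterbi-label fraction at the window containing the SNP
    and the mean posterior there.
    """
    wi = tracks.model.window_of_site(focal_site)
    carriers = np.nonzero(targets.H[:, focal_site] == allele)[0]
    if len(carriers) == 0:
        raise ValueError("no carriers of the requested allele")
    vit_frac = float((tracks.viterbi[carriers, wi] == 0).mean())
    post_mean = float(tracks.posterior_a[carriers, wi].mean())
    return {"viterbi_fraction_a": vit_frac, "posterior_mean_a": post_mean,
            "n_carriers": float(len(carriers))}
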