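"""Statistical scoring of candidate introns.

A candidate intron is summarized by a feature vector Z over its genomic
context — splice-signal class (GT-AG / GC-AG / AT-AC / other), the log
density of its size under an organism-specific Pareto intron-length model,
log size, the fraction of alignment mismatches in the supporting read, a
branch-point-sequence PWM score in the acceptor-proximal window, and the
length of the shorter exonic anchor.  A logistic regression trained on
annotated junctions (against constructed decoys) maps Z to a probability

    score = 1 / (1 + exp(-(b0 + b . Z)))

in (0, 1): large positive linear predictors give scores near 1, large
negative ones near 0.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._dna import N_CODE, encode, revcomp
from .io_formats import AnnotatedJunctionSet, Genome

logger = logging.getLogger(__name__)

# (class name, donor dinucleotide, acceptor dinucleotide) on the + strand;
# the - strand patterns are the reverse complements (GT..AG appears CT..AC).
SIGNAL_CLASSES: List[Tuple[str, str, str]] = [
    ("GT-AG", "GT", "AG"),
    ("GC-AG", "GC", "AG"),
    ("AT-AC", "AT", "AC"),
]

FEATURE_NAMES = [
    "sig_gtag",
    "sig_gcag",
    "sig_atac",
    "sig_other",
    "pareto_logpdf",
    "log_intron_size",
    "mismatch_frac",
    "bps_score",
    "anchor_len",
]

BPS_FLOOR = -10.0  # score assigned when no scorable branch-point window exists

# log-odds of one alignment mismatch: true junction (error/SNP ~1%/base)
# versus spurious placement (3/4 per base)
PER_MISMATCH_LOGODDS = math.log(0.01 / 0.75)

# Mammalian-consensus-derived branch-point PWM over a 7-nt motif
# (columns A, C, G, T; the branch A sits at position 3).
DEFAULT_BPS_PWM = np.array(
    [
        [0.05, 0.45, 0.05, 0.45],
        [0.02, 0.05, 0.02, 0.91],
        [0.25, 0.05, 0.45, 0.25],
        [0.92, 0.02, 0.04, 0.02],
        [0.05, 0.45, 0.05, 0.45],
        [0.15, 0.35, 0.15, 0.35],
        [0.25, 0.25, 0.25, 0.25],
    ]
)

# Search window for the branch point: 18-40 bp upstream of the 3' splice
# site, on the intron side.
BPS_WINDOW = (18, 40)


class DegenerateFitError(ValueError):
    """Raised when a distribution fit has no finite solution."""


def detect_signal(
    genome: Genome, chromosome: str, donor_end: int, acceptor_start: int
) -> Tuple[str, str]:
    """Splice-signal class and implied strand of an intron.

    Examines the first two and last two intronic bases: a forward-strand
    match of GT-AG/GC-AG/AT-AC returns (class, '+'); a match of the reverse
    complement pattern returns (class, '-'); otherwise ('other', '.').
    Introns shorter than 4 bp are ('other', '.').
    """
    seq = genome.sequences.get(chromosome)
    if seq is None or acceptor_start - donor_end < 4:
        return ("other", ".")
    first = seq[donor_end : donor_end + 2]
    last = seq[acceptor_start - 2 : acceptor_start]
    for name, dd, aa in SIGNAL_CLASSES:
        if first == dd and last == aa:
            return (name, "+")
    for name, dd, aa in SIGNAL_CLASSES:
        if first == revcomp(aa) and last == revcomp(dd):
            return (name, "-")
    return ("other", ".")


@dataclass(frozen=True)
class ParetoModel:
    """Intron-size law f(x) = alpha * xm^alpha / x^(alpha+1), x >= xm."""

    alpha: float
    xm: float

    def __post_init__(self):
        if self.alpha <= 0 or self.xm <= 0:
            raise ValueError("Pareto shape and scale must be positive")


def fit_pareto(
    intron_sizes: Sequence[float], xm: Optional[float] = None, min_n: int = 30
) -> ParetoModel:
    """Maximum-likelihood Pareto fit: xm = min observed size (or a configured
    floor), alpha = N / sum(ln(x_i / xm))."""
    sizes = np.asarray(intron_sizes, dtype=float)
    if len(sizes) < min_n:
        raise ValueError(
            f"need at least {min_n} intron sizes to fit the size model "
            "(use a packaged model for small annotations)"
        )
    if (sizes <= 0).any():
        raise ValueError("intron sizes must be positive")
    xm_hat = float(sizes.min()) if xm is None else float(xm)
    denom = float(np.log(sizes / xm_hat).sum())
    if denom <= 0:
        raise DegenerateFitError(
            "all intron sizes at the scale parameter; Pareto MLE diverges"
        )
    return ParetoModel(alpha=len(sizes) / denom, xm=xm_hat)


def pareto_log_density(
    model: ParetoModel, size: float, sub_support_penalty: float = 5.0
) -> float:
    """ln f(size) under the Pareto model.

    Sizes below the support floor xm get the density at xm minus a fixed
    penalty (they are shorter than the shortest annotated intron and should
    not outscore in-support sizes).
    """
    if size <= 0:
        raise ValueError("intron size must be positive")
    x = max(float(size), model.xm)
    val = (
        math.log(model.alpha)
        + model.alpha * math.log(model.xm)
        - (model.alpha + 1.0) * math.log(x)
    )
    if size < model.xm:
        val -= sub_support_penalty
    return val


def genome_background(genome: Genome) -> np.ndarray:
    """Strand-symmetric base composition of the genome (A=T, C=G pooled)."""
    counts = np.zeros(4, dtype=float)
    for arr in genome.arrays().values():
        bc = np.bincount(arr, minlength=5)[:4]
        counts += bc
    if counts.sum() == 0:
        return np.full(4, 0.25)
    at = (counts[0] + counts[3]) / 2.0
    cg = (counts[1] + counts[2]) / 2.0
    bg = np.array([at, cg, cg, at])
    return bg / bg.sum()


def _pwm_max_scan(codes: np.ndarray, logodds: np.ndarray) -> float:
    """Max sliding PWM log-odds over a code array; -inf if no valid window."""
    w = logodds.shape[0]
    n = len(codes)
    if n < w:
        return -math.inf
    best = -math.inf
    for s in range(n - w + 1):
        window = codes[s : s + w]
        if (window == N_CODE).any():
            continue
        score = float(logodds[np.arange(w), window].sum())
        if score > best:
            best = score
    return best


def score_bps(
    genome: Genome,
    chromosome: str,
    donor_end: int,
    acceptor_start: int,
    strand: str,
    pwm: Optional[np.ndarray] = None,
    background: Optional[np.ndarray] = None,
    floor: float = BPS_FLOOR,
) -> float:
    """Best branch-point PWM log-odds in the window 18-40 bp upstream of the
    3' splice site, on the intron side, strand-aware.

    For unresolved strands the better of the two orientations is returned.
    Scores fall back to ``floor`` when no scorable window exists.
    """
    pwm = DEFAULT_BPS_PWM if pwm is None else np.asarray(pwm, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    logodds = np.log(pwm) - np.log(bg)[None, :]
    arr = genome.arrays().get(chromosome)
    if arr is None:
        return floor
    lo, hi = BPS_WINDOW
    w = pwm.shape[0]
    best = -math.inf
    strands = ["+", "-"] if strand not in ("+", "-") else [strand]
    for st in strands:
        if st == "+":
            # motif fully inside [acceptor-40, acceptor-18), intron side only
            rs = max(donor_end, acceptor_start - hi, 0)
            re_ = max(rs, acceptor_start - lo)
            region = arr[rs:re_]
        else:
            # on '-' the biological 3' site is the genomic intron start;
            # upstream-intronic is [donor_end+18, donor_end+40), read on '-'
            rs = max(min(donor_end + lo, acceptor_start), 0)
            re_ = min(donor_end + hi, acceptor_start)
            region = _revcomp_codes(arr[rs:max(rs, re_)])
        score = _pwm_max_scan(region, logodds)
        best = max(best, score)
    return best if math.isfinite(best) else floor


_RC_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def _revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _RC_CODE[codes][::-1]


def extract_features(
    genome: Genome,
    chromosome: str,
    donor_end: int,
    acceptor_start: int,
    *,
    mismatches: int,
    read_length: int,
    anchor_len: int,
    pareto: ParetoModel,
    pwm: Optional[np.ndarray] = None,
    background: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, str, str]:
    """Raw (unstandardized) feature vector for an intron, with its signal
    class and implied strand."""
    signal, strand = detect_signal(genome, chromosome, donor_end, acceptor_start)
    size = acceptor_start - donor_end
    z = np.array(
        [
            1.0 if signal == "GT-AG" else 0.0,
            1.0 if signal == "GC-AG" else 0.0,
            1.0 if signal == "AT-AC" else 0.0,
            1.0 if signal == "other" else 0.0,
            pareto_log_density(pareto, size),
            math.log(size),
            mismatches / max(read_length, 1),
            score_bps(
                genome, chromosome, donor_end, acceptor_start, strand,
                pwm=pwm, background=background,
            ),
            float(anchor_len),
        ]
    )
    return z, signal, strand


@dataclass
class JunctionModel:
    """Trained per-organism scoring parameters.

    Holds the logistic intercept/coefficients (on standardized features, with
    the standardization constants), the Pareto intron-size model, the
    branch-point PWM and the background composition.  Serializes losslessly
    to versioned plain-text JSON.
    """

    organism: str
    feature_names: List[str]
    beta0: float
    beta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    pareto: ParetoModel
    bps_pwm: np.ndarray = field(default_factory=lambda: DEFAULT_BPS_PWM.copy())
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    read_length: int = 50
    version: str = "1"

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.beta) != len(self.feature_names):
            raise ValueError("coefficient vector length != feature vector length")

    def linear_predictor(self, z_raw: np.ndarray) -> float:
        zs = (np.asarray(z_raw, dtype=float) - self.mu) / self.sigma
        return float(self.beta0 + self.beta @ zs)

    def score(self, z_raw: np.ndarray) -> float:
        f = self.linear_predictor(z_raw)
        # clamp to avoid overflow and exact 0/1
        f = min(max(f, -700.0), 700.0)
        s = 1.0 / (1.0 + math.exp(-f))
        eps = 1e-12
        return min(max(s, eps), 1.0 - eps)

    def features(
        self,
        genome: Genome,
        chromosome: str,
        donor_end: int,
        acceptor_start: int,
        *,
        mismatches: int = 0,
        read_length: Optional[int] = None,
        anchor_len: Optional[int] = None,
    ) -> Tuple[np.ndarray, str, str]:
        rl = self.read_length if read_length is None else read_length
        al = rl // 2 if anchor_len is None else anchor_len
        return extract_features(
            genome,
            chromosome,
            donor_end,
            acceptor_start,
            mismatches=mismatches,
            read_length=rl,
            anchor_len=al,
            pareto=self.pareto,
            pwm=self.bps_pwm,
            background=self.background,
        )

    def save(self, path) -> None:
        payload = {
            "format": "spliceseek-junction-model",
            "version": self.version,
            "organism": self.organism,
            "feature_names": self.feature_names,
            "beta0": self.beta0,
            "beta": self.beta.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "pareto": {"alpha": self.pareto.alpha, "xm": self.pareto.xm},
            "bps_pwm": self.bps_pwm.tolist(),
            "background": self.background.tolist(),
            "read_length": self.read_length,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, path) -> "JunctionModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("format") != "spliceseek-junction-model":
            raise ValueError(f"{path} is not a junction model file")
        return cls(
            organism=d["organism"],
            feature_names=list(d["feature_names"]),
            beta0=float(d["beta0"]),
            beta=np.array(d["beta"]),
            mu=np.array(d["mu"]),
            sigma=np.array(d["sigma"]),
            pareto=ParetoModel(**d["pareto"]),
            bps_pwm=np.array(d["bps_pwm"]),
            background=np.array(d["background"]),
            read_length=int(d.get("read_length", 50)),
            version=str(d.get("version", "1")),
        )


def score_junction(model: JunctionModel, features: np.ndarray) -> float:
    """Logistic score 1/(1+exp(-f(Z))) of a raw feature vector."""
    return model.score(features)


def fit_logistic(
    X: np.ndarray, y: np.ndarray, l2: float = 1e-4, max_iter: int = 2000
) -> Tuple[float, np.ndarray]:
    """Maximum-likelihood logistic fit with a small L2 penalty.

    The penalty (lambda = ``l2``) guarantees convergence under perfect
    separation, which is logged as a warning when detected.
    """
    from sklearn.linear_model import LogisticRegression

    clf = LogisticRegression(C=1.0 / l2, max_iter=max_iter, solver="lbfgs")
    clf.fit(X, y)
    if (clf.predict(X) == y).all():
        logger.warning("training classes perfectly separated; L2 penalty active")
    return float(clf.intercept_[0]), clf.coef_[0].copy()


def make_decoys(
    junctions: Sequence[Tuple[str, int, int, str]],
    lengths: Dict[str, int],
    rng: np.random.Generator,
    n: Optional[int] = None,
    max_intron: int = 500_000,
    min_intron: int = 20,
) -> List[Tuple[str, int, int, str]]:
    """Hard negative junctions derived from annotated ones, two kinds:

    shifted (half) — one boundary moved by a random +-[3,50] nt offset
    (plausible position and size, scrambled signal); spurious (half) — a
    real donor paired with an acceptor at a random downstream locus, which
    is what a wrong local placement of a short fragment looks like.  Half
    the spurious sizes are bootstrapped from the annotated sizes (so splice
    signals and branch-point context, not size, set these apart) and half
    are uniform over the search span (teaching the size law of random
    placements; about 1/16 of spurious decoys carry a full canonical signal
    by chance, which calibrates the model on canonical-looking junk).
    Deterministic under the given RNG.
    """
    juncs = sorted(junctions)
    if not juncs:
        return []
    n = len(juncs) if n is None else n
    n_shift = n - n // 2
    decoys: List[Tuple[str, int, int, str]] = []
    attempts = 0
    while len(decoys) < n_shift and attempts < 20 * n_shift:
        attempts += 1
        c, s, e, st = juncs[int(rng.integers(len(juncs)))]
        delta = int(rng.integers(3, 51)) * (1 if rng.random() < 0.5 else -1)
        if rng.random() < 0.5:
            s2, e2 = s + delta, e
        else:
            s2, e2 = s, e + delta
        if 0 <= s2 < e2 <= lengths.get(c, 0) and (e2 - s2) <= max_intron:
            decoys.append((c, s2, e2, st))
    sizes = [e - s for (_, s, e, _) in juncs]
    attempts = 0
    while len(decoys) < n and attempts < 40 * n:
        attempts += 1
        c, s, e, st = juncs[int(rng.integers(len(juncs)))]
        # anchor a few nt off the real boundary, as a wrongly cut fragment
        # pair does; both boundary dinucleotides are then background sequence
        s2 = s + int(rng.integers(1, 6)) * (1 if rng.random() < 0.5 else -1)
        if rng.random() < 0.5:
            size = sizes[int(rng.integers(len(sizes)))] + int(rng.integers(-15, 16))
        else:
            size = int(rng.integers(min_intron, max_intron + 1))
        e2 = s2 + max(size, min_intron + 1)
        if 0 <= s2 < e2 <= lengths.get(c, 0):
            decoys.append((c, s2, e2, st))
    return decoys[:n]


def train_model(
    genome: Genome,
    annotation: AnnotatedJunctionSet,
    *,
    organism: str = "custom",
    seed: int = 0,
    read_length: int = 50,
    l2: float = 1e-4,
    pwm: Optional[np.ndarray] = None,
    max_intron: int = 500_000,
) -> Tuple[JunctionModel, "object"]:
    """Fit the Pareto size model and the logistic coefficients from an
    annotated junction set, against generated decoys.

    Returns the model and a per-feature coefficient report (DataFrame).
    """
    import pandas as pd

    juncs = sorted(annotation.junctions)
    sizes = [e - s for _, s, e, _ in juncs]
    pareto = fit_pareto(sizes)
    bg = genome_background(genome)
    pwm = DEFAULT_BPS_PWM if pwm is None else pwm

    rng = np.random.default_rng(seed)
    decoys = make_decoys(juncs, genome.lengths, rng, max_intron=max_intron)
    if not decoys:
        raise ValueError("could not construct decoy junctions for training")

    def _feats(items):
        rows = []
        for c, s, e, _ in items:
            z, _, _ = extract_features(
                genome, c, s, e,
                mismatches=0, read_length=read_length,
                anchor_len=read_length // 2,
                pareto=pareto, pwm=pwm, background=bg,
            )
            rows.append(z)
        return np.array(rows)

    Xp, Xn = _feats(juncs), _feats(decoys)
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(len(juncs)), np.zeros(len(decoys))])

    # The signal-class component is estimated by smoothed count log-odds
    # rather than free logistic coefficients, which behave badly for the
    # rare classes at annotation scale: with a handful of GC-AG/AT-AC
    # positives already explained by their size and branch-point context,
    # plain ML leaves the class coefficient near 0, while under complete
    # separation it diverges.  The three splice classes are partially pooled
    # toward their common log-odds (all three are genuine spliceosomal
    # signals; decoys reach the minor patterns by chance at ~1/256 per
    # boundary, so raw minor-class counts are dominated by that noise): each
    # class effect is shrunk toward the pooled splice effect with weight
    # n_pos / (n_pos + kappa), kappa = 20 positives.
    alpha_s = 2.0
    kappa = 20.0
    raw = np.zeros(4)
    npos_c = np.zeros(4)
    for ci in range(4):
        n_pos = float(Xp[:, ci].sum())
        n_neg = float(Xn[:, ci].sum())
        raw[ci] = math.log((n_pos + alpha_s) / (n_neg + alpha_s))
        npos_c[ci] = n_pos
    pooled = math.log(
        (npos_c[:3].sum() + alpha_s) / (float(Xn[:, :3].sum()) + alpha_s)
    )
    sig_offsets = raw.copy()
    for ci in range(3):
        w = npos_c[ci] / (npos_c[ci] + kappa)
        sig_offsets[ci] = w * raw[ci] + (1.0 - w) * pooled
    row_offset = X[:, :4] @ sig_offsets

    # Continuous features: standardized, fit by binomial GLM with the class
    # log-odds entering as a fixed offset (joint maximum likelihood given
    # the count-calibrated categorical part).
    mu = X.mean(axis=0)
    sigma = X.std(axis=0)
    sigma[sigma < 1e-9] = 1.0
    mu[:4] = 0.0
    sigma[:4] = 1.0
    cont = [i for i in range(4, X.shape[1]) if X[:, i].std() > 1e-9]
    Xc = (X[:, cont] - mu[cont]) / sigma[cont]
    import statsmodels.api as sm

    glm = sm.GLM(
        y, sm.add_constant(Xc, prepend=True), family=sm.families.Binomial(),
        offset=row_offset,
    )
    try:
        fit = glm.fit(maxiter=200)
        if not np.all(np.isfinite(fit.params)) or np.abs(fit.params).max() > 50:
            raise ValueError("unstable GLM fit")
    except Exception:
        logger.warning("GLM fit unstable (separation?); refitting with ridge")
        fit = glm.fit_regularized(alpha=max(l2, 1e-3), L1_wt=0.0)
    beta0 = float(fit.params[0])
    beta = np.zeros(X.shape[1])
    beta[:4] = sig_offsets
    for j, i in enumerate(cont):
        beta[i] = float(fit.params[1 + j])

    # The mismatch coefficient is not identifiable from annotation-derived
    # training data (every training intron has zero read mismatches), but
    # its value follows from the error model: under the true-junction
    # hypothesis a mismatch is a sequencing error or polymorphism (~1% per
    # base combined), under a spurious placement it occurs with probability
    # 3/4, so each mismatch costs ln(0.01/0.75) ~ -4.3 natural-log units.
    # The feature is mismatches/read_length, hence the scaling.
    mis_idx = FEATURE_NAMES.index("mismatch_frac")
    if X[:, mis_idx].std() <= 1e-9:
        beta[mis_idx] = PER_MISMATCH_LOGODDS * read_length

    model = JunctionModel(
        organism=organism,
        feature_names=list(FEATURE_NAMES),
        beta0=beta0,
        beta=beta,
        mu=mu,
        sigma=sigma,
        pareto=pareto,
        bps_pwm=np.asarray(pwm, dtype=float),
        background=bg,
        read_length=read_length,
    )
    report = pd.DataFrame({"feature": FEATURE_NAMES, "coefficient": beta})
    return model, report
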