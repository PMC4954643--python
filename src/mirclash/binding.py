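"""AGO binding preference model.

Sites are 6-mer seed matches in 3'UTRs, represented by (i) the 30-nt
sequences flanking the match upstream and downstream, scored with
positional weighted degree string kernels (k-mers up to degree 6), and
(ii) a positional context in the 3'UTR isoform structure — distances from
the site anchor (the base opposite miRNA nucleotide 2) to the UTR start
(stop codon), to the next isoform 3' end, and to the previous isoform 3'
end — scored with an RBF kernel on log-transformed distances. The two
sequence kernels and the positional kernel are summed (trace-normalized
per component by default) and a hinge-loss SVM is trained on the result.

Data sets from different cell types are combined with a multi-task
kernel, K_st(x, z) = (mu + delta_st) K(x, z): every pair of examples
shares the common term mu.K while same-task pairs gain an extra K. The
"common" discriminant (mu.K part only) gives a cell-type-agnostic score;
the per-task discriminant adds the task-specific part.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.svm import SVC

from .io import InputError, UtrRecord
from .trainset import LabeledSite, SeedMatch

PAD = "."
FLANK_WIDTH = 30
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def default_beta(degree: int = 6) -> np.ndarray:
    """Standard weighted-degree weights beta_k = 2(d-k+1)/(d(d+1))."""
    d = degree
    return np.array([2.0 * (d - k + 1) / (d * (d + 1)) for k in range(1, d + 1)])


@dataclass(frozen=True)
class FlankPair:
    """The 30-nt flanks of a seed match, padded with '.' at UTR boundaries.

    Both flanks are stored 5'->3' in UTR orientation: the downstream
    position nearest the seed faces miRNA nucleotide 1, the upstream
    position nearest the seed faces miRNA nucleotide 8. Padded symbols
    (and N) are excluded from every k-mer.
    """

    upstream: str
    downstream: str

    def __post_init__(self) -> None:
        if len(self.upstream) != FLANK_WIDTH or len(self.downstream) != FLANK_WIDTH:
            raise InputError(f"flanks must be {FLANK_WIDTH} nt")


@dataclass(frozen=True)
class PositionalContext:
    """Distances (nt) from the site anchor within the 3'UTR isoform map.

    ``d_prev_end`` is None when no isoform end lies 5' of the anchor; the
    kernel then substitutes the distance to the UTR start and sets an
    indicator component marking the sentinel.
    """

    d_stop: int
    d_next_end: int
    d_prev_end: int | None

    def __post_init__(self) -> None:
        if self.d_stop < 0 or self.d_next_end < 0:
            raise InputError("distances must be >= 0")
        if self.d_prev_end is not None and self.d_prev_end < 0:
            raise InputError("distances must be >= 0")


@dataclass(frozen=True)
class BindingExample:
    """One seed-match site, featurized for the binding model."""

    flanks: FlankPair
    context: PositionalContext
    task: str = "default"
    label: int = 0          # +1 / -1 / 0 (unlabeled, prediction only)
    site_id: str = ""


def extract_flanks(utr: UtrRecord, match: SeedMatch | LabeledSite,
                   width: int = FLANK_WIDTH) -> FlankPair:
    """30-nt upstream/downstream flanks of a seed match, pad-truncated."""
    start = match.match_start if isinstance(match, SeedMatch) else match.site_start
    end = match.match_end if isinstance(match, SeedMatch) else match.site_end
    seq = utr.sequence
    up = seq[max(0, start - width):start]
    down = seq[end:end + width]
    return FlankPair(upstream=up.rjust(width, PAD),
                     downstream=down.ljust(width, PAD))


def positional_context(utr: UtrRecord, anchor: int) -> PositionalContext:
    """Distances from the anchor to the UTR start and flanking isoform ends."""
    if not 0 <= anchor < len(utr.sequence):
        raise InputError(f"anchor {anchor} outside UTR {utr.transcript_id}")
    nxt = [e for e in utr.three_prime_ends if e >= anchor]
    prv = [e for e in utr.three_prime_ends if e < anchor]
    d_next = (min(nxt) - anchor) if nxt else 0
    d_prev = (anchor - max(prv)) if prv else None
    return PositionalContext(d_stop=anchor, d_next_end=d_next, d_prev_end=d_prev)


def make_binding_examples(sites: Sequence[LabeledSite],
                          utrs: Sequence[UtrRecord],
                          width: int = FLANK_WIDTH) -> list[BindingExample]:
    utr_by_id = {u.transcript_id: u for u in utrs}
    out = []
    for s in sites:
        utr = utr_by_id[s.transcript_id]
        out.append(BindingExample(
            flanks=extract_flanks(utr, s, width),
            context=positional_context(utr, s.anchor_position),
            task=s.task,
            label=+1 if s.label == "positive" else -1,
            site_id=f"{s.transcript_id}:{s.site_start}-{s.site_end}:{s.family}"))
    return out


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def encode_flank(seq: str) -> np.ndarray:
    """Integer encoding; pads and N become -1 and never match anything."""
    return np.array([_BASE_CODE.get(c, -1) for c in seq], dtype=np.int8)


def wd_kernel(a: str, z: str, degree: int = 6,
              beta: np.ndarray | None = None) -> float:
    """Weighted degree string kernel between two equal-length sequences.

    k(a, z) = sum_k beta_k sum_j [a and z share the k-mer at position j];
    k-mers touching a pad or N never match.
    """
    if len(a) != len(z):
        raise InputError("wd_kernel requires equal-length sequences")
    if beta is None:
        beta = default_beta(degree)
    ea, ez = encode_flank(a), encode_flank(z)
    m = (ea == ez) & (ea >= 0)
    total = 0.0
    run = 0
    runs = []
    for v in m:
        if v:
            run += 1
        elif run:
            runs.append(run)
            run = 0
    if run:
        runs.append(run)
    for r in runs:
        for k in range(1, min(degree, r) + 1):
            total += beta[k - 1] * (r - k + 1)
    return total


def _wd_matrix(A: np.ndarray, B: np.ndarray, degree: int,
               beta: np.ndarray) -> np.ndarray:
    """WD kernel matrix between rows of two encoded sequence arrays."""
    M = (A[:, None, :] == B[None, :, :]) & (A[:, None, :] >= 0) & (B[None, :, :] >= 0)
    M = M.astype(np.float32)
    K = np.zeros(M.shape[:2], dtype=np.float64)
    S = np.cumsum(M, axis=-1)
    L = M.shape[-1]
    for k in range(1, degree + 1):
        win = S[..., k - 1:].copy()
        win[..., 1:] -= S[..., :L - k]
        K += beta[k - 1] * (win > k - 0.5).sum(axis=-1)
    return K


def transform_context(c: PositionalContext) -> np.ndarray:
    """log10(1 + distance) per component plus a sentinel indicator.

    Raw nt distances span four orders of magnitude; the log transform
    keeps a single RBF width meaningful across that range.
    """
    d_prev = c.d_stop if c.d_prev_end is None else c.d_prev_end
    return np.array([math.log10(1 + c.d_stop),
                     math.log10(1 + c.d_next_end),
                     math.log10(1 + d_prev),
                     1.0 if c.d_prev_end is None else 0.0])


def positional_kernel(c1: PositionalContext, c2: PositionalContext,
                      gamma: float = 1.0) -> float:
    """RBF kernel on the transformed positional-context vectors."""
    if gamma <= 0:
        raise InputError("gamma must be > 0")
    d = transform_context(c1) - transform_context(c2)
    return float(np.exp(-gamma * float(d @ d)))


def _rbf_matrix(T1: np.ndarray, T2: np.ndarray, gamma: float) -> np.ndarray:
    sq = ((T1[:, None, :] - T2[None, :, :]) ** 2).sum(axis=-1)
    return np.exp(-gamma * sq)


@dataclass
class KernelMatrix:
    """A summed kernel with its recoverable components."""

    matrix: np.ndarray
    components: dict[str, np.ndarray]
    tags: tuple[str, ...]


def _featurize_set(examples: Sequence[BindingExample]):
    Eu = np.stack([encode_flank(e.flanks.upstream) for e in examples])
    Ed = np.stack([encode_flank(e.flanks.downstream) for e in examples])
    T = np.stack([transform_context(e.context) for e in examples])
    return Eu, Ed, T


def combined_kernel(examples: Sequence[BindingExample], degree: int = 6,
                    beta: np.ndarray | None = None, gamma: float = 1.0,
                    normalize: bool = True,
                    use_sequence: bool = True,
                    use_positional: bool = True) -> KernelMatrix:
    """K = K_wd_up + K_wd_down + K_positional on one example set.

    Components are trace-normalized to mean diagonal 1 before summation by
    default so no component dominates by scale (``normalize=False`` sums
    the raw matrices).
    """
    if beta is None:
        beta = default_beta(degree)
    Eu, Ed, T = _featurize_set(examples)
    comps = {}
    if use_sequence:
        comps["wd_up"] = _wd_matrix(Eu, Eu, degree, beta)
        comps["wd_down"] = _wd_matrix(Ed, Ed, degree, beta)
    if use_positional:
        comps["positional"] = _rbf_matrix(T, T, gamma)
    if normalize:
        for tag, K in comps.items():
            c = float(np.trace(K)) / len(examples)
            if c > 0:
                comps[tag] = K / c
    total = sum(comps.values())
    return KernelMatrix(matrix=total, components=comps, tags=tuple(comps))


def multitask_kernel(K: KernelMatrix | np.ndarray, tasks: Sequence[str],
                     mu: float) -> KernelMatrix:
    """Entry-wise (mu + 1[same task]) scaling of a base kernel."""
    if mu < 0:
        raise InputError("mu must be >= 0")
    base = K.matrix if isinstance(K, KernelMatrix) else np.asarray(K)
    t = np.asarray(tasks)
    if len(t) != base.shape[0]:
        raise InputError("tasks must align with the kernel")
    same = (t[:, None] == t[None, :]).astype(float)
    out = (mu + same) * base
    comps = dict(K.components) if isinstance(K, KernelMatrix) else {}
    comps = {tag: (mu + same) * c for tag, c in comps.items()}
    return KernelMatrix(matrix=out, components=comps,
                        tags=tuple(comps) or ("combined",))


# ---------------------------------------------------------------------------
# training / prediction
# ---------------------------------------------------------------------------

MU_GRID = (0.1, 0.25, 0.5, 1.0, 2.0, 4.0)


@dataclass
class BindingTrainConfig:
    C: float = 1.0
    mu: float | str = 1.0        # "auto": select on MU_GRID by 5-fold CV
    gamma: float = 1.0
    degree: int = 6
    cv_folds: int = 5
    rng_seed: int = 0
    normalize: bool = True
    use_sequence: bool = True
    use_positional: bool = True
    multitask: bool | None = None   # None: multitask iff >1 task present


@dataclass
class BindingModel:
    """Dual-form kernel SVM over stored training examples."""

    examples: list[BindingExample]
    dual_coef: np.ndarray          # alpha_i * y_i on support examples
    support: np.ndarray            # indices into examples
    bias: float
    mu: float | None               # None: single-task (no task structure)
    gamma: float
    degree: int
    beta: np.ndarray
    norms: dict[str, float]        # per-component trace normalizers
    tasks: tuple[str, ...]
    config: dict = field(default_factory=dict)
    _train_feats: tuple | None = None

    def _features(self):
        if self._train_feats is None:
            sup = [self.examples[i] for i in self.support]
            self._train_feats = _featurize_set(sup)
        return self._train_feats

    def kernel_to(self, examples: Sequence[BindingExample]) -> dict[str, np.ndarray]:
        """Component kernels between support examples (rows) and new examples."""
        Eu, Ed, T = self._features()
        Xu, Xd, Xt = _featurize_set(examples)
        comps = {}
        if "wd_up" in self.norms:
            comps["wd_up"] = _wd_matrix(Eu, Xu, self.degree, self.beta) \
                / self.norms["wd_up"]
            comps["wd_down"] = _wd_matrix(Ed, Xd, self.degree, self.beta) \
                / self.norms["wd_down"]
        if "positional" in self.norms:
            comps["positional"] = _rbf_matrix(T, Xt, self.gamma) \
                / self.norms["positional"]
        return comps

    def to_json(self, path: str | Path) -> None:
        """Versioned JSON with a sidecar TSV of support examples."""
        path = Path(path)
        doc = {"format": "mirclash-binding-model", "version": 1,
               "dual_coef": self.dual_coef.tolist(),
               "support": self.support.tolist(),
               "bias": self.bias, "mu": self.mu, "gamma": self.gamma,
               "degree": self.degree, "beta": self.beta.tolist(),
               "norms": self.norms, "tasks": list(self.tasks),
               "config": self.config,
               "support_table": str(path.name) + ".support.tsv"}
        path.write_text(json.dumps(doc, indent=1))
        side = path.parent / (path.name + ".support.tsv")
        with open(side, "w") as fh:
            fh.write("# index\tupstream\tdownstream\td_stop\td_next_end\t"
                     "d_prev_end\ttask\tlabel\tsite_id\n")
            for i, e in enumerate(self.examples):
                c = e.context
                prev = "." if c.d_prev_end is None else str(c.d_prev_end)
                fh.write(f"{i}\t{e.flanks.upstream}\t{e.flanks.downstream}\t"
                         f"{c.d_stop}\t{c.d_next_end}\t{prev}\t{e.task}\t"
                         f"{e.label}\t{e.site_id}\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "BindingModel":
        path = Path(path)
        doc = json.loads(path.read_text())
        if doc.get("format") != "mirclash-binding-model":
            raise InputError(f"{path}: not a binding model file")
        examples = []
        side = path.parent / doc["support_table"]
        with open(side) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                f = line.rstrip("\n").split("\t")
                prev = None if f[5] == "." else int(f[5])
                examples.append(BindingExample(
                    FlankPair(f[1], f[2]),
                    PositionalContext(int(f[3]), int(f[4]), prev),
                    f[6], int(f[7]), f[8]))
        return cls(examples=examples,
                   dual_coef=np.array(doc["dual_coef"]),
                   support=np.array(doc["support"], dtype=int),
                   bias=doc["bias"], mu=doc["mu"], gamma=doc["gamma"],
                   degree=doc["degree"], beta=np.array(doc["beta"]),
                   norms=doc["norms"], tasks=tuple(doc["tasks"]),
                   config=doc["config"])


def _assemble_kernel(examples, cfg: BindingTrainConfig, mu: float | None):
    beta = default_beta(cfg.degree)
    raw = combined_kernel(examples, cfg.degree, beta, cfg.gamma,
                          normalize=False,
                          use_sequence=cfg.use_sequence,
                          use_positional=cfg.use_positional)
    norms, comps = {}, {}
    for tag, comp in raw.components.items():
        c = float(np.trace(comp)) / len(examples) if cfg.normalize else 1.0
        norms[tag] = c if c > 0 else 1.0
        comps[tag] = comp / norms[tag]
    K = sum(comps.values())
    if mu is not None:
        t = np.array([e.task for e in examples])
        K = (mu + (t[:, None] == t[None, :]).astype(float)) * K
    return K, norms, beta


def train_binding(examples: Sequence[BindingExample],
                  config: BindingTrainConfig | None = None) -> BindingModel:
    """Fit the (multi-task) kernel hinge-loss SVM on featurized sites.

    With a single task present (or ``multitask=False``) a regular SVM is
    fit on the combined kernel; ``mu="auto"`` selects the task-coupling
    weight on a fixed grid by stratified 5-fold CV maximizing mean
    held-out auROC.
    """
    import logging
    cfg = config or BindingTrainConfig()
    examples = list(examples)
    y = np.array([e.label for e in examples], dtype=float)
    if set(y.tolist()) != {-1.0, 1.0}:
        raise InputError("both classes required")
    tasks = sorted({e.task for e in examples})
    multitask = cfg.multitask if cfg.multitask is not None else len(tasks) > 1
    if multitask and len(tasks) < 2:
        logging.getLogger(__name__).warning(
            "multitask requested with a single task; falling back to single-task")
        multitask = False
    mu: float | None
    if not multitask:
        mu = None
    elif cfg.mu == "auto":
        mu = _select_mu(examples, y, cfg)
    else:
        mu = float(cfg.mu)

    K, norms, beta = _assemble_kernel(examples, cfg, mu)
    clf = SVC(kernel="precomputed", C=cfg.C)
    clf.fit(K, y)
    return BindingModel(examples=examples,
                        dual_coef=clf.dual_coef_.ravel().copy(),
                        support=clf.support_.copy(),
                        bias=float(clf.intercept_[0]),
                        mu=mu, gamma=cfg.gamma, degree=cfg.degree, beta=beta,
                        norms=norms, tasks=tuple(tasks),
                        config={"C": cfg.C, "mu": mu, "gamma": cfg.gamma,
                                "degree": cfg.degree,
                                "normalize": cfg.normalize,
                                "use_sequence": cfg.use_sequence,
                                "use_positional": cfg.use_positional,
                                "multitask": multitask})


def _select_mu(examples, y, cfg: BindingTrainConfig) -> float:
    from sklearn.model_selection import StratifiedKFold
    from sklearn.metrics import roc_auc_score
    tasks = [e.task for e in examples]
    task_idx = {t: i for i, t in enumerate(sorted(set(tasks)))}
    strata = np.array([2 * task_idx[t] + (1 if lab > 0 else 0)
                       for t, lab in zip(tasks, y)])
    skf = StratifiedKFold(n_splits=cfg.cv_folds, shuffle=True,
                          random_state=cfg.rng_seed % (2**31))
    beta = default_beta(cfg.degree)
    base = combined_kernel(examples, cfg.degree, beta, cfg.gamma,
                           normalize=cfg.normalize,
                           use_sequence=cfg.use_sequence,
                           use_positional=cfg.use_positional)
    best_mu, best_auc = MU_GRID[0], -1.0
    for mu in MU_GRID:
        Km = multitask_kernel(base, tasks, mu).matrix
        aucs = []
        for tr, te in skf.split(np.zeros(len(y)), strata):
            clf = SVC(kernel="precomputed", C=cfg.C)
            clf.fit(Km[np.ix_(tr, tr)], y[tr])
            dec = clf.decision_function(Km[np.ix_(te, tr)])
            if len(set(y[te].tolist())) == 2:
                aucs.append(roc_auc_score(y[te], dec))
        mean = float(np.mean(aucs)) if aucs else -1.0
        if mean > best_auc:
            best_auc, best_mu = mean, mu
    return best_mu


def predict_binding(model: BindingModel,
                    examples: Sequence[BindingExample] | BindingExample,
                    mode: str = "common") -> np.ndarray | float:
    """Discriminant scores for new examples.

    ``mode="common"``: f(x) = sum_i alpha_i y_i mu K(x_i, x) + b (the
    cell-type-agnostic part). ``mode="task:<id>"``: adds the
    task-specific kernel share for a registered task. For a single-task
    model both modes equal the plain SVM discriminant.
    """
    single = isinstance(examples, BindingExample)
    exs = [examples] if single else list(examples)
    comps = model.kernel_to(exs)
    K = sum(comps.values())  # support x new
    if model.mu is None:
        weight = np.ones((len(model.support), 1))
    elif mode == "common":
        weight = np.full((len(model.support), 1), model.mu)
    elif mode.startswith("task:"):
        t = mode.split(":", 1)[1]
        if t not in model.tasks:
            raise InputError(f"unknown task {t!r}")
        sup_tasks = np.array([model.examples[i].task for i in model.support])
        weight = (model.mu + (sup_tasks == t).astype(float))[:, None]
    else:
        raise InputError(f"unknown mode {mode!r}")
    f = (model.dual_coef[:, None] * weight * K).sum(axis=0) + model.bias
    return float(f[0]) if single else f


# ---------------------------------------------------------------------------
# score combination and gene-level aggregation
# ---------------------------------------------------------------------------

@dataclass
class CombinedScorer:
    """Combine duplex and binding scores into a single ranking.

    ``sum_z`` z-scores each component against its training distribution
    and adds; ``min_rank``/``product_rank`` combine within-set ranks.
    """

    scheme: str = "sum_z"
    duplex_mean: float = 0.0
    duplex_std: float = 1.0
    binding_mean: float = 0.0
    binding_std: float = 1.0
    fitted: bool = False

    def fit(self, duplex_scores: Sequence[float],
            binding_scores: Sequence[float]) -> "CombinedScorer":
        d = np.asarray(duplex_scores, dtype=float)
        b = np.asarray(binding_scores, dtype=float)
        self.duplex_mean, self.duplex_std = float(d.mean()), float(d.std() or 1.0)
        self.binding_mean, self.binding_std = float(b.mean()), float(b.std() or 1.0)
        self.fitted = True
        return self

    def combine(self, duplex_scores, binding_scores) -> np.ndarray:
        if not self.fitted:
            raise InputError("CombinedScorer must be fitted before combining")
        d = np.asarray(duplex_scores, dtype=float)
        b = np.asarray(binding_scores, dtype=float)
        if self.scheme == "sum_z":
            return (d - self.duplex_mean) / self.duplex_std \
                + (b - self.binding_mean) / self.binding_std
        rd = rankdata(d)
        rb = rankdata(b)
        if self.scheme == "min_rank":
            return np.minimum(rd, rb)
        if self.scheme == "product_rank":
            return rd * rb
        raise InputError(f"unknown scheme {self.scheme!r}")


def combine_scores(duplex_score, binding_score,
                   scorer: CombinedScorer) -> float | np.ndarray:
    out = scorer.combine(np.atleast_1d(duplex_score),
                         np.atleast_1d(binding_score))
    return float(out[0]) if np.isscalar(duplex_score) else out


def gene_level_score(site_scores_by_gene: dict[str, Sequence[float]]
                     ) -> dict[str, float]:
    """Per-gene score: the highest site score (empty genes are excluded)."""
    return {g: float(max(scores)) for g, scores in site_scores_by_gene.items()
            if len(scores) > 0}
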