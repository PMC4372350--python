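"""Linear-chain conditional random field for per-residue core labeling.

The model assigns a label sequence Y = (y_1..y_n) to an observation
sequence X (the eight feature tracks) through

    P(Y | X) = exp( sum_i sum_j lambda_j f_j(y_{i-1}, y_i, x, i) ) / Z(X)

where each f_j is either a *state* feature s_j(y_i, x, i) — an instantiated
observation pattern paired with a label — or a *transition* feature
t_j(y_{i-1}, y_i, x, i), and Z(X) sums the exponentiated score over all
label sequences.  Inference (forward-backward, Viterbi) is exact and done
in log space; training maximizes the L2-regularized conditional likelihood
with L-BFGS.  A virtual BEGIN label anchors transitions at position 0.

Observation patterns are instantiated from CRF++-style ``U``/``B``
templates referencing track columns at offsets within the size-5 window.
Every distinct observed pattern is paired with every label (unigram) or
label bigram (bigram), mirroring the common toolkit's behavior.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .features import CHANNELS, FeatureTracks

LABELS = ("CRITICAL", "NONCRITICAL")

_TERM_RE = re.compile(r"%x\[(-?\d+),(\d+)\]")


class TemplateError(ValueError):
    pass


@dataclass(frozen=True)
class FeatureTemplate:
    """One U/B rule: which track columns, at which offsets, feed a feature."""

    template_id: str
    arity: str  # "unigram" | "bigram"
    terms: tuple[tuple[int, int], ...]  # (offset, column) pairs; empty for pure B

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(CHANNELS[col] for _, col in self.terms)


def parse_template_line(line: str) -> FeatureTemplate | None:
    line = line.strip()
    if not line or line.startswith("#"):
        return None
    if ":" in line:
        tid, body = line.split(":", 1)
    else:
        tid, body = line, ""
    if not tid or tid[0] not in "UB":
        raise TemplateError(f"template id must start with U or B: {line!r}")
    terms = []
    consumed = body
    for m in _TERM_RE.finditer(body):
        off, col = int(m.group(1)), int(m.group(2))
        if col >= len(CHANNELS):
            raise TemplateError(f"column {col} out of range in {line!r}")
        terms.append((off, col))
        consumed = consumed.replace(m.group(0), "", 1)
    if consumed.replace("/", "").strip():
        raise TemplateError(f"unparsed template text in {line!r}")
    arity = "unigram" if tid[0] == "U" else "bigram"
    if arity == "unigram" and not terms:
        raise TemplateError(f"unigram template without observation terms: {line!r}")
    return FeatureTemplate(template_id=tid, arity=arity, terms=tuple(terms))


def parse_templates(text: str) -> list[FeatureTemplate]:
    out = []
    for line in text.splitlines():
        t = parse_template_line(line)
        if t is not None:
            out.append(t)
    if not out:
        raise TemplateError("empty template set")
    return out


def load_templates(name_or_path: str) -> list[FeatureTemplate]:
    """Load a packaged template set (``default``, ``reduced``) or a file path."""
    from importlib import resources as importlib_resources

    if name_or_path in ("default", "reduced"):
        text = (
            importlib_resources.files("ampcore.data")
            .joinpath(f"templates/{name_or_path}.txt")
            .read_text()
        )
    else:
        with open(name_or_path) as fh:
            text = fh.read()
    return parse_templates(text)


def drop_channel(
    templates: Sequence[FeatureTemplate], channel: str
) -> list[FeatureTemplate]:
    """Ablation helper: remove every template referencing ``channel``."""
    col = CHANNELS.index(channel)
    kept = [t for t in templates if all(c != col for _, c in t.terms)]
    if not any(t.arity == "unigram" for t in kept):
        raise TemplateError(f"removing {channel} leaves no state features")
    return kept


def _pad_token(pos: int, n: int) -> str:
    # CRF++-style boundary tokens encode how far outside the sequence we are
    return f"_B{pos}_" if pos < 0 else f"_B+{pos - n + 1}_"


def compile_observations(
    tracks: FeatureTracks, templates: Sequence[FeatureTemplate]
) -> tuple[list[list[str]], list[list[str]]]:
    """Instantiate every template at every position of one sequence.

    Returns ``(uni, bi)``: per-position lists of observation strings, one
    per unigram (resp. bigram) template, in template order.  Out-of-range
    offsets yield explicit boundary padding tokens so the model sees
    begin/end context.
    """
    n = tracks.length
    uni_templates = [t for t in templates if t.arity == "unigram"]
    bi_templates = [t for t in templates if t.arity == "bigram"]
    uni: list[list[str]] = []
    bi: list[list[str]] = []
    for i in range(n):
        row_u, row_b = [], []
        for tset, row in ((uni_templates, row_u), (bi_templates, row_b)):
            for t in tset:
                vals = []
                for off, col in t.terms:
                    p = i + off
                    if 0 <= p < n:
                        vals.append(tracks.channels[CHANNELS[col]][p])
                    else:
                        vals.append(_pad_token(p, n))
                row.append(f"{t.template_id}={'/'.join(vals)}")
        uni.append(row_u)
        bi.append(row_b)
    return uni, bi


@dataclass
class CRFModel:
    """A trained linear-chain CRF: indexed features plus their weights."""

    labels: tuple[str, ...]
    templates: list[FeatureTemplate]
    uni_index: dict[str, int]
    bi_index: dict[str, int]
    w_uni: np.ndarray  # (n_uni_patterns, L)
    w_bi: np.ndarray  # (n_bi_patterns, L+1, L); row L of axis 1 = BEGIN
    l2_sigma2: float = 10.0

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    @property
    def n_weights(self) -> int:
        return self.w_uni.size + self.w_bi.size

    def label_ids(self, labels: Sequence[str]) -> np.ndarray:
        try:
            return np.array([self.labels.index(l) for l in labels], dtype=np.intp)
        except ValueError:
            bad = sorted(set(labels) - set(self.labels))
            raise ValueError(f"unknown labels {bad}") from None

    # -- per-sequence scoring --------------------------------------------

    def _ids(self, tracks: FeatureTracks) -> tuple[np.ndarray, np.ndarray]:
        uni, bi = compile_observations(tracks, self.templates)
        nu, nb = len(self.uni_index), len(self.bi_index)
        u = np.array(
            [[self.uni_index.get(s, nu) for s in row] for row in uni], dtype=np.intp
        ).reshape(tracks.length, -1)
        b = np.array(
            [[self.bi_index.get(s, nb) for s in row] for row in bi], dtype=np.intp
        ).reshape(tracks.length, -1)
        return u, b

    def _scores(self, tracks: FeatureTracks) -> tuple[np.ndarray, np.ndarray]:
        """(node, edge): (n, L) state scores and (n, L+1, L) transition scores."""
        u, b = self._ids(tracks)
        lab = self.n_labels
        w_u = np.vstack([self.w_uni, np.zeros((1, lab))])
        w_b = np.concatenate(
            [self.w_bi, np.zeros((1, lab + 1, lab))], axis=0
        )
        node = w_u[u].sum(axis=1)
        edge = w_b[b].sum(axis=1)
        return node, edge


@dataclass(frozen=True)
class InferenceResult:
    path: tuple[str, ...]
    path_log_score: float
    log_partition: float
    marginals: np.ndarray  # (n, L)


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    m = a.max(axis=axis, keepdims=True)
    return (m + np.log(np.exp(a - m).sum(axis=axis, keepdims=True))).squeeze(axis)


def path_log_score(model: CRFModel, tracks: FeatureTracks, y: Sequence[str]) -> float:
    """Sum of fired feature weights along one label path (BEGIN-anchored)."""
    if len(y) != tracks.length:
        raise ValueError(f"{len(y)} labels for length {tracks.length}")
    ids = model.label_ids(y)
    node, edge = model._scores(tracks)
    lab = model.n_labels
    score = node[np.arange(tracks.length), ids].sum()
    score += edge[0, lab, ids[0]]
    if tracks.length > 1:
        t = np.arange(1, tracks.length)
        score += edge[t, ids[:-1], ids[1:]].sum()
    return float(score)


def log_partition(model: CRFModel, tracks: FeatureTracks) -> float:
    """log Z(X) by the forward recursion in log space."""
    node, edge = model._scores(tracks)
    alpha = _forward(node, edge, model.n_labels)
    return float(_lse(alpha[-1], axis=0))


def _forward(node: np.ndarray, edge: np.ndarray, lab: int) -> np.ndarray:
    n = node.shape[0]
    alpha = np.empty((n, lab))
    alpha[0] = node[0] + edge[0, lab, :]
    for t in range(1, n):
        alpha[t] = _lse(alpha[t - 1][:, None] + edge[t, :lab, :], axis=0) + node[t]
    return alpha


def _backward(node: np.ndarray, edge: np.ndarray, lab: int) -> np.ndarray:
    n = node.shape[0]
    beta = np.zeros((n, lab))
    for t in range(n - 2, -1, -1):
        beta[t] = _lse(edge[t + 1, :lab, :] + (node[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


def viterbi(model: CRFModel, tracks: FeatureTracks) -> list[str]:
    """Highest-scoring label path; ties resolve toward the first label."""
    node, edge = model._scores(tracks)
    lab = model.n_labels
    n = tracks.length
    delta = np.empty((n, lab))
    back = np.zeros((n, lab), dtype=np.intp)
    delta[0] = node[0] + edge[0, lab, :]
    for t in range(1, n):
        cand = delta[t - 1][:, None] + edge[t, :lab, :]
        back[t] = cand.argmax(axis=0)  # argmax takes the first max: tie-break
        delta[t] = cand[back[t], np.arange(lab)] + node[t]
    path = np.empty(n, dtype=np.intp)
    path[-1] = int(delta[-1].argmax())
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return [model.labels[i] for i in path]


def marginals(model: CRFModel, tracks: FeatureTracks) -> np.ndarray:
    """Per-position label posteriors P(y_i | X) by forward-backward."""
    node, edge = model._scores(tracks)
    alpha = _forward(node, edge, model.n_labels)
    beta = _backward(node, edge, model.n_labels)
    logz = _lse(alpha[-1], axis=0)
    return np.exp(alpha + beta - logz)


def infer(model: CRFModel, tracks: FeatureTracks) -> InferenceResult:
    path = viterbi(model, tracks)
    return InferenceResult(
        path=tuple(path),
        path_log_score=path_log_score(model, tracks, path),
        log_partition=log_partition(model, tracks),
        marginals=marginals(model, tracks),
    )


# -- training -----------------------------------------------------------------


@dataclass
class _Compiled:
    """Batched, padded, integer-indexed training corpus."""

    u: np.ndarray  # (S, maxlen, Tu) pattern ids; sentinel = n_uni
    b: np.ndarray  # (S, maxlen, Tb)
    gold: np.ndarray  # (S, maxlen) label ids, 0-padded
    lengths: np.ndarray  # (S,)
    n_uni: int
    n_bi: int


def _compile_dataset(
    dataset: Sequence[tuple[FeatureTracks, Sequence[str]]],
    templates: Sequence[FeatureTemplate],
    labels: Sequence[str],
) -> tuple[_Compiled, dict[str, int], dict[str, int]]:
    uni_index: dict[str, int] = {}
    bi_index: dict[str, int] = {}
    per_seq = []
    label_pos = {l: i for i, l in enumerate(labels)}
    for tracks, gold in dataset:
        if len(gold) != tracks.length:
            raise ValueError(
                f"{tracks.sequence_id}: {len(gold)} labels for length {tracks.length}"
            )
        uni, bi = compile_observations(tracks, templates)
        u_ids = [[uni_index.setdefault(s, len(uni_index)) for s in row] for row in uni]
        b_ids = [[bi_index.setdefault(s, len(bi_index)) for s in row] for row in bi]
        per_seq.append((u_ids, b_ids, [label_pos[l] for l in gold]))

    n_uni, n_bi = len(uni_index), len(bi_index)
    lengths = np.array([len(g) for _, _, g in per_seq], dtype=np.intp)
    maxlen = int(lengths.max())
    s_count = len(per_seq)
    tu = len(per_seq[0][0][0]) if per_seq[0][0] else 0
    tb = len(per_seq[0][1][0]) if per_seq[0][1] else 0
    u = np.full((s_count, maxlen, tu), n_uni, dtype=np.intp)
    b = np.full((s_count, maxlen, tb), n_bi, dtype=np.intp)
    gold = np.zeros((s_count, maxlen), dtype=np.intp)
    for s, (u_ids, b_ids, g) in enumerate(per_seq):
        n = len(g)
        if tu:
            u[s, :n] = u_ids
        if tb:
            b[s, :n] = b_ids
        gold[s, :n] = g
    return _Compiled(u, b, gold, lengths, n_uni, n_bi), uni_index, bi_index


def _batched_nll_grad(
    w_uni: np.ndarray, w_bi: np.ndarray, data: _Compiled, lab: int, sigma2: float
) -> tuple[float, np.ndarray, np.ndarray]:
    """Regularized NLL and its gradient over the whole (padded) corpus."""
    s_count, maxlen, _ = data.u.shape
    labp = lab + 1  # + virtual BEGIN
    w_u = np.vstack([w_uni, np.zeros((1, lab))])
    w_b = np.concatenate([w_bi, np.zeros((1, labp, lab))], axis=0)
    node = w_u[data.u].sum(axis=2)  # (S, T, L)
    edge = w_b[data.b].sum(axis=2)  # (S, T, L+1, L)

    valid = np.arange(maxlen)[None, :] < data.lengths[:, None]  # (S, T)
    last = data.lengths - 1

    # forward with carry at padded positions
    alpha = np.empty((s_count, maxlen, lab))
    alpha[:, 0] = node[:, 0] + edge[:, 0, lab, :]
    for t in range(1, maxlen):
        cand = alpha[:, t - 1, :, None] + edge[:, t, :lab, :]
        m = cand.max(axis=1)
        new = m + np.log(np.exp(cand - m[:, None, :]).sum(axis=1)) + node[:, t]
        alpha[:, t] = np.where(valid[:, t, None], new, alpha[:, t - 1])
    logz = _lse(alpha[np.arange(s_count), last], axis=1)  # (S,)

    beta = np.zeros((s_count, maxlen, lab))
    for t in range(maxlen - 2, -1, -1):
        nxt = node[:, t + 1] + beta[:, t + 1]
        cand = edge[:, t + 1, :lab, :] + nxt[:, None, :]
        m = cand.max(axis=2)
        new = m + np.log(np.exp(cand - m[:, :, None]).sum(axis=2))
        inside = (t <= data.lengths - 2)[:, None]
        beta[:, t] = np.where(inside, new, 0.0)

    # position marginals and adjacent-pair marginals
    marg = np.exp(alpha + beta - logz[:, None, None])
    marg[~valid] = 0.0
    pair = np.exp(
        alpha[:, :-1, :, None]
        + edge[:, 1:, :lab, :]
        + (node[:, 1:] + beta[:, 1:])[:, :, None, :]
        - logz[:, None, None, None]
    )
    pair[~valid[:, 1:]] = 0.0

    # expected minus empirical feature counts
    g_uni = np.zeros((data.n_uni + 1, lab))
    g_bi = np.zeros((data.n_bi + 1, labp, lab))
    tu = data.u.shape[2]
    tb = data.b.shape[2]
    flat_u = data.u.reshape(-1)
    gold_onehot = np.zeros((s_count, maxlen, lab))
    gv = valid & True
    gold_onehot[np.arange(s_count)[:, None], np.arange(maxlen)[None, :], data.gold] = 1.0
    gold_onehot[~valid] = 0.0
    du = marg - gold_onehot  # (S, T, L)
    for y in range(lab):
        wts = np.broadcast_to(du[:, :, y][:, :, None], data.u.shape).reshape(-1)
        g_uni[:, y] = np.bincount(flat_u, weights=wts, minlength=data.n_uni + 1)

    if tb:
        # transitions at t >= 1
        gold_pair = np.zeros_like(pair)
        sidx = np.arange(s_count)[:, None]
        tidx = np.arange(maxlen - 1)[None, :]
        gold_pair[sidx, tidx, data.gold[:, :-1], data.gold[:, 1:]] = 1.0
        gold_pair[~valid[:, 1:]] = 0.0
        dpair = pair - gold_pair
        flat_b1 = data.b[:, 1:, :].reshape(-1)
        for yp in range(lab):
            for y in range(lab):
                wts = np.broadcast_to(
                    dpair[:, :, yp, y][:, :, None], data.b[:, 1:, :].shape
                ).reshape(-1)
                g_bi[:, yp, y] = np.bincount(
                    flat_b1, weights=wts, minlength=data.n_bi + 1
                )
        # BEGIN transitions at t = 0
        d0 = marg[:, 0] - gold_onehot[:, 0]  # (S, L)
        flat_b0 = data.b[:, 0, :].reshape(-1)
        for y in range(lab):
            wts = np.broadcast_to(d0[:, y][:, None], data.b[:, 0, :].shape).reshape(-1)
            g_bi[:, lab, y] += np.bincount(
                flat_b0, weights=wts, minlength=data.n_bi + 1
            )

    # gold path score
    node_g = np.take_along_axis(node, data.gold[:, :, None], axis=2)[:, :, 0]
    node_g[~valid] = 0.0
    score = node_g.sum()
    sidx = np.arange(s_count)
    score += edge[sidx, 0, lab, data.gold[:, 0]].sum()
    if maxlen > 1:
        e_g = edge[
            sidx[:, None],
            np.arange(1, maxlen)[None, :],
            data.gold[:, :-1],
            data.gold[:, 1:],
        ]
        e_g[~valid[:, 1:]] = 0.0
        score += e_g.sum()

    nll = float(logz.sum() - score)
    # L2 prior
    nll += float((w_uni**2).sum() + (w_bi**2).sum()) / (2.0 * sigma2)
    g_u = g_uni[:-1] + w_uni / sigma2
    g_b = g_bi[:-1] + w_bi / sigma2
    return nll, g_u, g_b


def nll_and_gradient(
    model: CRFModel, dataset: Sequence[tuple[FeatureTracks, Sequence[str]]]
) -> tuple[float, np.ndarray]:
    """Regularized negative conditional log-likelihood and its gradient.

    The gradient is (model-expected - empirical) feature counts plus the
    L2 term, flattened in (unigram block, bigram block) order.
    """
    data, uni_index, bi_index = _compile_dataset(
        dataset, model.templates, model.labels
    )
    # remap model weights onto this dataset's pattern index; unseen -> 0
    lab = model.n_labels
    w_uni = np.zeros((data.n_uni, lab))
    for s, i in uni_index.items():
        j = model.uni_index.get(s)
        if j is not None:
            w_uni[i] = model.w_uni[j]
    w_bi = np.zeros((data.n_bi, lab + 1, lab))
    for s, i in bi_index.items():
        j = model.bi_index.get(s)
        if j is not None:
            w_bi[i] = model.w_bi[j]
    nll, g_u, g_b = _batched_nll_grad(w_uni, w_bi, data, lab, model.l2_sigma2)
    # map gradient back to the model's own index (unseen patterns get the
    # pure regularization pull)
    out_u = model.w_uni / model.l2_sigma2
    for s, i in uni_index.items():
        j = model.uni_index.get(s)
        if j is not None:
            out_u[j] = g_u[i]
    out_b = model.w_bi / model.l2_sigma2
    for s, i in bi_index.items():
        j = model.bi_index.get(s)
        if j is not None:
            out_b[j] = g_b[i]
    return nll, np.concatenate([out_u.reshape(-1), out_b.reshape(-1)])


@dataclass
class TrainResult:
    model: CRFModel
    final_nll: float
    n_iterations: int
    converged: bool


def train(
    dataset: Sequence[tuple[FeatureTracks, Sequence[str]]],
    templates: Sequence[FeatureTemplate] | str = "default",
    l2_sigma2: float = 10.0,
    max_iter: int = 200,
    tol: float = 1e-6,
    seed: int | None = None,
    labels: Sequence[str] = LABELS,
    init: np.ndarray | None = None,
) -> TrainResult:
    """Fit CRF weights by L-BFGS on the regularized conditional likelihood.

    Weights start at zero (the objective is convex, so the optimum does not
    depend on the start and no randomness enters training; ``seed`` is
    accepted for interface symmetry and ignored).  ``init`` overrides the
    zero start, e.g. for convexity smoke tests.
    """
    if not dataset:
        raise ValueError("empty training dataset")
    if isinstance(templates, str):
        templates = load_templates(templates)
    templates = list(templates)
    if not any(t.arity == "unigram" for t in templates):
        raise TemplateError("template set has no state features")
    data, uni_index, bi_index = _compile_dataset(dataset, templates, labels)
    lab = len(labels)
    nu, nb = data.n_uni, data.n_bi

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        w_uni = x[: nu * lab].reshape(nu, lab)
        w_bi = x[nu * lab :].reshape(nb, lab + 1, lab)
        nll, g_u, g_b = _batched_nll_grad(w_uni, w_bi, data, lab, l2_sigma2)
        if not np.isfinite(nll):
            raise FloatingPointError(
                f"non-finite objective (nll={nll}); weights norm "
                f"{np.linalg.norm(x):.3g}"
            )
        return nll, np.concatenate([g_u.reshape(-1), g_b.reshape(-1)])

    x0 = np.zeros(nu * lab + nb * (lab + 1) * lab)
    if init is not None:
        x0 = np.asarray(init, dtype=float).copy()
    res = minimize(
        objective,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-5},
    )
    w_uni = res.x[: nu * lab].reshape(nu, lab)
    w_bi = res.x[nu * lab :].reshape(nb, lab + 1, lab)
    model = CRFModel(
        labels=tuple(labels),
        templates=templates,
        uni_index=uni_index,
        bi_index=bi_index,
        w_uni=w_uni,
        w_bi=w_bi,
        l2_sigma2=l2_sigma2,
    )
    return TrainResult(
        model=model,
        final_nll=float(res.fun),
        n_iterations=int(res.nit),
        converged=bool(res.success),
    )


# -- model serialization -------------------------------------------------------

_FORMAT_HEADER = "ampcore-crf\tv1"


def save_model(model: CRFModel, path) -> None:
    """Versioned text serialization; round-trips weights bit-exactly."""
    lines = [_FORMAT_HEADER]
    lines.append("labels\t" + "\t".join(model.labels))
    lines.append(f"sigma2\t{model.l2_sigma2!r}")
    lines.append(f"templates\t{len(model.templates)}")
    for t in model.templates:
        body = "/".join(f"%x[{off},{col}]" for off, col in t.terms)
        lines.append(f"{t.template_id}:{body}" if body else t.template_id)
    lines.append(f"uni\t{len(model.uni_index)}")
    inv_u = sorted(model.uni_index, key=model.uni_index.get)
    for s in inv_u:
        w = model.w_uni[model.uni_index[s]]
        lines.append(s + "\t" + "\t".join(repr(float(v)) for v in w))
    lines.append(f"bi\t{len(model.bi_index)}")
    inv_b = sorted(model.bi_index, key=model.bi_index.get)
    for s in inv_b:
        w = model.w_bi[model.bi_index[s]].reshape(-1)
        lines.append(s + "\t" + "\t".join(repr(float(v)) for v in w))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def load_model(path) -> CRFModel:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if lines[0] != _FORMAT_HEADER:
        raise ValueError(f"not an ampcore CRF model file: {path}")
    labels = tuple(lines[1].split("\t")[1:])
    sigma2 = float(lines[2].split("\t")[1])
    n_templates = int(lines[3].split("\t")[1])
    pos = 4
    templates = [parse_template_line(lines[pos + i]) for i in range(n_templates)]
    pos += n_templates
    lab = len(labels)
    tag, n_uni_s = lines[pos].split("\t")
    assert tag == "uni"
    n_uni = int(n_uni_s)
    pos += 1
    uni_index: dict[str, int] = {}
    w_uni = np.zeros((n_uni, lab))
    for i in range(n_uni):
        parts = lines[pos + i].split("\t")
        uni_index[parts[0]] = i
        w_uni[i] = [float(v) for v in parts[1:]]
    pos += n_uni
    tag, n_bi_s = lines[pos].split("\t")
    assert tag == "bi"
    n_bi = int(n_bi_s)
    pos += 1
    bi_index: dict[str, int] = {}
    w_bi = np.zeros((n_bi, lab + 1, lab))
    for i in range(n_bi):
        parts = lines[pos + i].split("\t")
        bi_index[parts[0]] = i
        w_bi[i] = np.array([float(v) for v in parts[1:]]).reshape(lab + 1, lab)
    return CRFModel(
        labels=labels,
        templates=templates,
        uni_index=uni_index,
        bi_index=bi_index,
        w_uni=w_uni,
        w_bi=w_bi,
        l2_sigma2=sigma2,
    )
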