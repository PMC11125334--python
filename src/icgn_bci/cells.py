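"""Recurrent cell primitives: classic LSTM and the integrated contextual gate cell.

Both cells are implemented from scratch on top of NumPy so that every gate,
state update and gradient is explicit and verifiable.

The classic LSTM follows the standard formulation

    F_t = sigmoid(Wxf x_t + Whf h_{t-1} + b_f)
    I_t = sigmoid(Wxi x_t + Whi h_{t-1} + b_i)
    O_t = sigmoid(Wxo x_t + Who h_{t-1} + b_o)
    G_t = tanh   (Wxc x_t + Whc h_{t-1} + b_c)      # candidate
    C_t = F_t * C_{t-1} + I_t * G_t
    H_t = O_t * tanh(C_t)

The integrated contextual gate (ICGN) cell feeds the previous cell state into
every gate and into the candidate, and replaces the additive memory update by
the candidate scaled with the *sum* of the three gate activations:

    I_t = sigmoid(Wxi x_t + Whi h_{t-1} + Wci c_{t-1} + b_i)
    F_t = sigmoid(Wxf x_t + Whf h_{t-1} + Wcf c_{t-1} + b_f)
    O_t = sigmoid(Wxo x_t + Who h_{t-1} + Wco c_{t-1} + b_o)
    G_t = tanh   (Wxc x_t + Whc h_{t-1} + Wcc c_{t-1} + b_c)
    C_t = (F_t + I_t + O_t) * G_t
    H_t = O_t * tanh(C_t)

Note that the ICGN memory update carries no direct ``C_{t-1}`` term: the
previous cell state influences the next step only through the gate and
candidate pre-activations.  A direct consequence is the bound
``|C_t| < 3`` (three gates, each < 1, times a candidate with |G| < 1) and
hence ``|H_t| < tanh(3)``.

Cell-context weights are full ``H x H`` matrices by default (matrix-product
notation); a diagonal variant in the spirit of classic peephole connections
is available at initialisation time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterator

import numpy as np

__all__ = [
    "CellParameters",
    "CellState",
    "GateTrace",
    "init_cell_parameters",
    "lstm_step",
    "icgn_step",
    "unroll",
    "bidirectional_unroll",
    "cell_gradients",
    "finite_difference_gradients",
    "gradient_check",
    "SquaredLoss",
]

_GATES = ("i", "f", "o", "c")  # c = candidate


@dataclass
class CellState:
    """Pair of per-timestep state vectors: cell/memory state ``c`` and hidden state ``h``."""

    c: np.ndarray
    h: np.ndarray

    @classmethod
    def zeros(cls, hidden_dim: int) -> "CellState":
        return cls(c=np.zeros(hidden_dim), h=np.zeros(hidden_dim))


@dataclass
class GateTrace:
    """Gate activations of a single step: input, forget, output in (0,1), candidate in (-1,1)."""

    i: np.ndarray
    f: np.ndarray
    o: np.ndarray
    candidate: np.ndarray


@dataclass
class CellParameters:
    """All weight matrices and biases of one recurrent cell.

    Input weights ``wx*`` have shape (H, D), hidden weights ``wh*`` and
    cell-context weights ``wc*`` have shape (H, H), biases have shape (H,).
    Cell-context weights exist only for ``cell_kind='icgn'``.

    ``share_candidate_with_forget`` aliases the candidate parameters with the
    forget-gate parameters (the candidate pre-activation literally reuses the
    forget-gate weights); ``share_output_context_with_forget`` aliases the
    output gate's cell-context matrix with the forget gate's.  Aliased arrays
    are the *same* ndarray object, so gradients are accumulated jointly.
    """

    cell_kind: str
    input_dim: int
    hidden_dim: int
    wxi: np.ndarray
    wxf: np.ndarray
    wxo: np.ndarray
    wxc: np.ndarray
    whi: np.ndarray
    whf: np.ndarray
    who: np.ndarray
    whc: np.ndarray
    bi: np.ndarray
    bf: np.ndarray
    bo: np.ndarray
    bc: np.ndarray
    wci: np.ndarray | None = None
    wcf: np.ndarray | None = None
    wco: np.ndarray | None = None
    wcc: np.ndarray | None = None
    share_candidate_with_forget: bool = False
    share_output_context_with_forget: bool = False
    candidate_uses_cell_context: bool = True

    def __post_init__(self) -> None:
        if self.cell_kind not in ("lstm", "icgn"):
            raise ValueError(f"unknown cell_kind {self.cell_kind!r}")
        D, H = self.input_dim, self.hidden_dim
        for name in ("wxi", "wxf", "wxo", "wxc"):
            self._check_shape(name, (H, D))
        for name in ("whi", "whf", "who", "whc"):
            self._check_shape(name, (H, H))
        for name in ("bi", "bf", "bo", "bc"):
            self._check_shape(name, (H,))
        if self.cell_kind == "icgn":
            for name in ("wci", "wcf", "wco", "wcc"):
                self._check_shape(name, (H, H))
        else:
            if any(getattr(self, n) is not None for n in ("wci", "wcf", "wco", "wcc")):
                raise ValueError("cell-context weights are only valid for the icgn cell")

    def _check_shape(self, name: str, shape: tuple[int, ...]) -> None:
        arr = getattr(self, name)
        if arr is None or arr.shape != shape:
            raise ValueError(f"parameter {name} must have shape {shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"parameter {name} contains non-finite values")

    def named_arrays(self) -> dict[str, np.ndarray]:
        """Unique trainable arrays keyed by canonical name (aliases collapsed)."""
        names = ["wxi", "whi", "bi", "wxf", "whf", "bf", "wxo", "who", "bo"]
        if not self.share_candidate_with_forget:
            names += ["wxc", "whc", "bc"]
        if self.cell_kind == "icgn":
            names += ["wci", "wcf"]
            if not self.share_output_context_with_forget:
                names.append("wco")
            if self.candidate_uses_cell_context and not self.share_candidate_with_forget:
                names.append("wcc")
        return {n: getattr(self, n) for n in names}

    def copy(self) -> "CellParameters":
        kw = {}
        alias_map = {}
        if self.share_candidate_with_forget:
            alias_map.update({"wxc": "wxf", "whc": "whf", "bc": "bf", "wcc": "wcf"})
        if self.share_output_context_with_forget:
            alias_map["wco"] = "wcf"
        arrays = {}
        for name in ("wxi", "wxf", "wxo", "wxc", "whi", "whf", "who", "whc",
                     "bi", "bf", "bo", "bc", "wci", "wcf", "wco", "wcc"):
            src = getattr(self, name)
            if src is None:
                arrays[name] = None
                continue
            canonical = alias_map.get(name, name)
            if canonical not in arrays or arrays[canonical] is None:
                arrays[canonical] = np.array(getattr(self, canonical), copy=True)
            arrays[name] = arrays[canonical]
        kw.update(arrays)
        return CellParameters(
            cell_kind=self.cell_kind,
            input_dim=self.input_dim,
            hidden_dim=self.hidden_dim,
            share_candidate_with_forget=self.share_candidate_with_forget,
            share_output_context_with_forget=self.share_output_context_with_forget,
            candidate_uses_cell_context=self.candidate_uses_cell_context,
            **kw,
        )


def init_cell_parameters(
    cell_kind: str,
    input_dim: int,
    hidden_dim: int,
    init_scheme: str = "uniform_scaled",
    seed: int | np.random.Generator = 0,
    forget_bias: float = 0.0,
    share_candidate_with_forget: bool = False,
    share_output_context_with_forget: bool = False,
    candidate_uses_cell_context: bool = True,
    diagonal_cell_context: bool = False,
) -> CellParameters:
    """Create a fresh, reproducibly initialised parameter set.

    ``init_scheme`` is one of ``zeros``, ``uniform_scaled`` (uniform on
    ``[-1/sqrt(fan_in), 1/sqrt(fan_in)]``) or ``normal_scaled``
    (``N(0, 1/fan_in)``).  Biases start at zero except for an optional
    forget-gate offset.  ``diagonal_cell_context`` restricts the icgn
    cell-context matrices to their diagonal at initialisation.
    """
    if input_dim < 1 or hidden_dim < 1:
        raise ValueError("input_dim and hidden_dim must be positive")
    if init_scheme not in ("zeros", "uniform_scaled", "normal_scaled"):
        raise ValueError(f"unknown init_scheme {init_scheme!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    D, H = input_dim, hidden_dim

    def draw(shape: tuple[int, ...], fan_in: int) -> np.ndarray:
        if init_scheme == "zeros":
            return np.zeros(shape)
        scale = 1.0 / np.sqrt(fan_in)
        if init_scheme == "uniform_scaled":
            return rng.uniform(-scale, scale, size=shape)
        return rng.normal(0.0, scale, size=shape)

    arrs: dict[str, np.ndarray | None] = {}
    for g in _GATES:
        arrs[f"wx{g}"] = draw((H, D), D)
        arrs[f"wh{g}"] = draw((H, H), H)
        arrs[f"b{g}"] = np.zeros(H)
    arrs["bf"] = arrs["bf"] + forget_bias
    if cell_kind == "icgn":
        for g in _GATES:
            w = draw((H, H), H)
            if diagonal_cell_context:
                w = np.diag(np.diag(w))
            arrs[f"wc{g}"] = w
    else:
        for g in _GATES:
            arrs[f"wc{g}"] = None

    if share_candidate_with_forget:
        arrs["wxc"] = arrs["wxf"]
        arrs["whc"] = arrs["whf"]
        arrs["bc"] = arrs["bf"]
        if cell_kind == "icgn":
            arrs["wcc"] = arrs["wcf"]
    if share_output_context_with_forget and cell_kind == "icgn":
        arrs["wco"] = arrs["wcf"]

    return CellParameters(
        cell_kind=cell_kind,
        input_dim=D,
        hidden_dim=H,
        wxi=arrs["wxi"], wxf=arrs["wxf"], wxo=arrs["wxo"], wxc=arrs["wxc"],
        whi=arrs["whi"], whf=arrs["whf"], who=arrs["who"], whc=arrs["whc"],
        bi=arrs["bi"], bf=arrs["bf"], bo=arrs["bo"], bc=arrs["bc"],
        wci=arrs["wci"], wcf=arrs["wcf"], wco=arrs["wco"], wcc=arrs["wcc"],
        share_candidate_with_forget=share_candidate_with_forget,
        share_output_context_with_forget=share_output_context_with_forget,
        candidate_uses_cell_context=candidate_uses_cell_context,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


# ---------------------------------------------------------------------------
# batched forward steps (x: (N, D); h, c: (N, H))
# ---------------------------------------------------------------------------

def _lstm_step_batch(p: CellParameters, x, h, c):
    i = _sigmoid(x @ p.wxi.T + h @ p.whi.T + p.bi)
    f = _sigmoid(x @ p.wxf.T + h @ p.whf.T + p.bf)
    o = _sigmoid(x @ p.wxo.T + h @ p.who.T + p.bo)
    g = np.tanh(x @ p.wxc.T + h @ p.whc.T + p.bc)
    c_new = f * c + i * g
    tc = np.tanh(c_new)
    h_new = o * tc
    cache = (x, h, c, i, f, o, g, c_new, tc)
    return h_new, c_new, i, f, o, g, cache


def _icgn_step_batch(p: CellParameters, x, h, c):
    i = _sigmoid(x @ p.wxi.T + h @ p.whi.T + c @ p.wci.T + p.bi)
    f = _sigmoid(x @ p.wxf.T + h @ p.whf.T + c @ p.wcf.T + p.bf)
    o = _sigmoid(x @ p.wxo.T + h @ p.who.T + c @ p.wco.T + p.bo)
    zg = x @ p.wxc.T + h @ p.whc.T + p.bc
    if p.candidate_uses_cell_context:
        zg = zg + c @ p.wcc.T
    g = np.tanh(zg)
    c_new = (f + i + o) * g
    tc = np.tanh(c_new)
    h_new = o * tc
    cache = (x, h, c, i, f, o, g, c_new, tc)
    return h_new, c_new, i, f, o, g, cache


def _step_batch(p: CellParameters, x, h, c):
    if p.cell_kind == "lstm":
        return _lstm_step_batch(p, x, h, c)
    return _icgn_step_batch(p, x, h, c)


def _validate_step_inputs(p: CellParameters, x_t, state: CellState) -> None:
    if x_t.shape != (p.input_dim,):
        raise ValueError(f"x_t must have shape ({p.input_dim},), got {x_t.shape}")
    if state.c.shape != (p.hidden_dim,) or state.h.shape != (p.hidden_dim,):
        raise ValueError(f"state vectors must have shape ({p.hidden_dim},)")
    if not (np.all(np.isfinite(x_t)) and np.all(np.isfinite(state.c)) and np.all(np.isfinite(state.h))):
        raise ValueError("non-finite input to cell step")


def lstm_step(params: CellParameters, x_t: np.ndarray, prev_state: CellState) -> tuple[CellState, GateTrace]:
    """One LSTM step: additive memory update gated by forget/input, output-gated hidden state."""
    if params.cell_kind != "lstm":
        raise ValueError("lstm_step requires cell_kind='lstm'")
    x_t = np.asarray(x_t, dtype=float)
    _validate_step_inputs(params, x_t, prev_state)
    h, c, i, f, o, g, _ = _lstm_step_batch(params, x_t[None, :], prev_state.h[None, :], prev_state.c[None, :])
    return CellState(c=c[0], h=h[0]), GateTrace(i=i[0], f=f[0], o=o[0], candidate=g[0])


def icgn_step(params: CellParameters, x_t: np.ndarray, prev_state: CellState) -> tuple[CellState, GateTrace]:
    """One integrated-contextual-gate step.

    All three gates and the candidate receive the previous cell state; the new
    memory state is ``(F+I+O) * candidate`` with no direct previous-cell carry
    term, so ``|C_t| < 3`` always holds.
    """
    if params.cell_kind != "icgn":
        raise ValueError("icgn_step requires cell_kind='icgn'")
    x_t = np.asarray(x_t, dtype=float)
    _validate_step_inputs(params, x_t, prev_state)
    h, c, i, f, o, g, _ = _icgn_step_batch(params, x_t[None, :], prev_state.h[None, :], prev_state.c[None, :])
    return CellState(c=c[0], h=h[0]), GateTrace(i=i[0], f=f[0], o=o[0], candidate=g[0])


def _unroll_batch(p: CellParameters, X: np.ndarray, h0=None, c0=None, keep_cache=False):
    """Run a cell over a batch of sequences.  X: (N, T, D).  Returns (H_seq (N,T,H), h_T, c_T, caches)."""
    N, T, D = X.shape
    if D != p.input_dim:
        raise ValueError(f"input dim mismatch: expected {p.input_dim}, got {D}")
    H = p.hidden_dim
    h = np.zeros((N, H)) if h0 is None else h0
    c = np.zeros((N, H)) if c0 is None else c0
    H_seq = np.empty((N, T, H))
    caches = [] if keep_cache else None
    for t in range(T):
        h, c, *_rest, cache = _step_batch(p, X[:, t, :], h, c)
        H_seq[:, t, :] = h
        if keep_cache:
            caches.append(cache)
    return H_seq, h, c, caches


def unroll(
    params: CellParameters,
    sequence: np.ndarray,
    initial_state: CellState | None = None,
) -> tuple[np.ndarray, CellState]:
    """Apply the cell over a (T, D) sequence; returns the (T, H) hidden trace and final state."""
    X = np.asarray(sequence, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("sequence must be a (T, D) array with T >= 1")
    if not np.all(np.isfinite(X)):
        raise ValueError("sequence contains non-finite values")
    state = initial_state or CellState.zeros(params.hidden_dim)
    H_seq, h, c, _ = _unroll_batch(params, X[None], state.h[None, :].copy(), state.c[None, :].copy())
    return H_seq[0], CellState(c=c[0], h=h[0])


def bidirectional_unroll(
    forward_params: CellParameters,
    backward_params: CellParameters,
    sequence: np.ndarray,
) -> np.ndarray:
    """Forward pass and time-reversed backward pass, concatenated per timestep to (T, 2H)."""
    if (forward_params.input_dim, forward_params.hidden_dim) != (
        backward_params.input_dim,
        backward_params.hidden_dim,
    ):
        raise ValueError("forward and backward parameter dimensions must match")
    X = np.asarray(sequence, dtype=float)
    fwd, _ = unroll(forward_params, X)
    bwd, _ = unroll(backward_params, X[::-1])
    return np.concatenate([fwd, bwd[::-1]], axis=1)


# ---------------------------------------------------------------------------
# backpropagation through time
# ---------------------------------------------------------------------------

def _zero_grads(p: CellParameters) -> dict[str, np.ndarray]:
    return {name: np.zeros_like(arr) for name, arr in p.named_arrays().items()}


def _bptt_batch(
    p: CellParameters,
    caches: list,
    d_hseq: np.ndarray,
    d_h_final: np.ndarray | None = None,
    d_c_final: np.ndarray | None = None,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Backward pass through a cached forward unroll.

    ``d_hseq``: gradient of the loss w.r.t. every hidden output, (N, T, H);
    optional extra gradients on the final hidden/cell state.  Returns
    (parameter gradients keyed like ``named_arrays``, gradient w.r.t. X).
    """
    N, T, H = d_hseq.shape
    grads = _zero_grads(p)
    dX = np.empty((N, T, p.input_dim))
    dh_next = np.zeros((N, H))
    dc_next = np.zeros((N, H))
    if d_h_final is not None:
        dh_next = dh_next + d_h_final
    if d_c_final is not None:
        dc_next = dc_next + d_c_final

    share_cand = p.share_candidate_with_forget
    share_out_ctx = p.share_output_context_with_forget

    for t in range(T - 1, -1, -1):
        x, h_prev, c_prev, i, f, o, g, c_new, tc = caches[t]
        dh = d_hseq[:, t, :] + dh_next
        dc = dc_next

        dc_total = dc + dh * o * (1.0 - tc * tc)
        if p.cell_kind == "lstm":
            do = dh * tc
            df = dc_total * c_prev
            di = dc_total * g
            dg = dc_total * i
            dc_prev = dc_total * f
        else:
            gate_sum = f + i + o
            do = dh * tc + dc_total * g
            df = dc_total * g
            di = dc_total * g
            dg = dc_total * gate_sum
            dc_prev = np.zeros_like(dc_total)

        da_i = di * i * (1.0 - i)
        da_f = df * f * (1.0 - f)
        da_o = do * o * (1.0 - o)
        da_g = dg * (1.0 - g * g)

        # parameter gradients; candidate/alias folding below
        acc = {
            "wxi": da_i.T @ x, "whi": da_i.T @ h_prev, "bi": da_i.sum(0),
            "wxf": da_f.T @ x, "whf": da_f.T @ h_prev, "bf": da_f.sum(0),
            "wxo": da_o.T @ x, "who": da_o.T @ h_prev, "bo": da_o.sum(0),
        }
        cand = {"wxc": da_g.T @ x, "whc": da_g.T @ h_prev, "bc": da_g.sum(0)}
        if p.cell_kind == "icgn":
            acc["wci"] = da_i.T @ c_prev
            acc["wcf"] = da_f.T @ c_prev
            wco_g = da_o.T @ c_prev
            if share_out_ctx:
                acc["wcf"] = acc["wcf"] + wco_g
            else:
                acc["wco"] = wco_g
            if p.candidate_uses_cell_context:
                cand["wcc"] = da_g.T @ c_prev
        if share_cand:
            acc["wxf"] = acc["wxf"] + cand["wxc"]
            acc["whf"] = acc["whf"] + cand["whc"]
            acc["bf"] = acc["bf"] + cand["bc"]
            if p.cell_kind == "icgn" and p.candidate_uses_cell_context:
                acc["wcf"] = acc["wcf"] + cand["wcc"]
        else:
            acc.update(cand)
        for k, v in acc.items():
            grads[k] += v

        dx = da_i @ p.wxi + da_f @ p.wxf + da_o @ p.wxo + da_g @ p.wxc
        dh_prev = da_i @ p.whi + da_f @ p.whf + da_o @ p.who + da_g @ p.whc
        if p.cell_kind == "icgn":
            dc_prev = dc_prev + da_i @ p.wci + da_f @ p.wcf + da_o @ p.wco
            if p.candidate_uses_cell_context:
                dc_prev = dc_prev + da_g @ p.wcc
        dX[:, t, :] = dx
        dh_next = dh_prev
        dc_next = dc_prev

    return grads, dX


@dataclass
class SquaredLoss:
    """Half sum-of-squares loss on the hidden trace, on the final step or the full sequence."""

    target: np.ndarray
    on: str = "final"  # or "sequence"

    def value_and_grad(self, h_seq: np.ndarray) -> tuple[float, np.ndarray]:
        d = np.zeros_like(h_seq)
        if self.on == "final":
            r = h_seq[-1] - self.target
            d[-1] = r
            return 0.5 * float(np.sum(r * r)), d
        r = h_seq - self.target
        return 0.5 * float(np.sum(r * r)), r


def cell_gradients(
    params: CellParameters,
    sequence: np.ndarray,
    loss_spec: SquaredLoss | Callable[[np.ndarray], tuple[float, np.ndarray]],
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss value and exact BPTT gradients for one (T, D) sequence.

    ``loss_spec`` is either a :class:`SquaredLoss` or any callable mapping the
    (T, H) hidden trace to ``(loss, d_loss/d_hidden_trace)``.  The gradients
    are keyed like :meth:`CellParameters.named_arrays` and match central
    finite differences to first order.
    """
    X = np.asarray(sequence, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("sequence must be a (T, D) array with T >= 1")
    fn = loss_spec.value_and_grad if hasattr(loss_spec, "value_and_grad") else loss_spec
    H_seq, _, _, caches = _unroll_batch(params, X[None], keep_cache=True)
    loss, d_hseq = fn(H_seq[0])
    grads, _ = _bptt_batch(params, caches, np.asarray(d_hseq)[None])
    return loss, grads


def finite_difference_gradients(
    params: CellParameters,
    sequence: np.ndarray,
    loss_spec,
    eps: float = 1e-6,
) -> dict[str, np.ndarray]:
    """Central-finite-difference gradients; the independent check for :func:`cell_gradients`."""
    fn = loss_spec.value_and_grad if hasattr(loss_spec, "value_and_grad") else loss_spec

    def loss_of(p: CellParameters) -> float:
        H_seq, _ = unroll(p, sequence)
        return fn(H_seq)[0]

    out: dict[str, np.ndarray] = {}
    work = params.copy()
    for name, arr in work.named_arrays().items():
        g = np.zeros_like(arr)
        it = np.nditer(arr, flags=["multi_index"])
        while not it.finished:
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = loss_of(work)
            arr[idx] = orig - eps
            lm = loss_of(work)
            arr[idx] = orig
            g[idx] = (lp - lm) / (2.0 * eps)
            it.iternext()
        out[name] = g
    return out


def gradient_check(
    params: CellParameters,
    sequence: np.ndarray,
    loss_spec,
    eps: float = 1e-6,
) -> float:
    """Worst per-array relative error between BPTT and central finite differences.

    Relative error is norm-based, ``||g - g_fd|| / max(||g||, ||g_fd||)``,
    the standard well-conditioned gradient-check metric.
    """
    _, g = cell_gradients(params, sequence, loss_spec)
    fd = finite_difference_gradients(params, sequence, loss_spec, eps=eps)
    worst = 0.0
    for name in g:
        denom = max(np.linalg.norm(g[name]), np.linalg.norm(fd[name]), 1e-12)
        worst = max(worst, float(np.linalg.norm(g[name] - fd[name]) / denom))
    return worst
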