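"""Independent straight-loop reference implementations.

Everything here is written with plain Python loops and the math module so
it shares no code path with the package: it re-derives the architecture
from its definition and serves as the ground truth the vectorized
implementation is checked against.
"""

import math


def softmax_row(row):
    m = max(row)
    exps = [math.exp(v - m) for v in row]
    s = sum(exps)
    return [v / s for v in exps]


def mha_loops(x, wq, wk, wv, wo):
    """Full-width multi-head attention on one [d, F] token matrix.

    wq/wk/wv: [n][F][F]; wo: [n*F][F].  Every head keeps the full feature
    width F, scores are scaled by sqrt(F), head outputs are concatenated
    and projected by wo.
    """
    d = len(x)
    F = len(x[0])
    n = len(wq)

    def matmul(a, b):  # [p x q] @ [q x r]
        return [[sum(a[i][k] * b[k][j] for k in range(len(b)))
                 for j in range(len(b[0]))] for i in range(len(a))]

    heads = []
    for h in range(n):
        q = matmul(x, wq[h])
        k = matmul(x, wk[h])
        v = matmul(x, wv[h])
        scores = [[sum(q[i][f] * k[j][f] for f in range(F)) / math.sqrt(F)
                   for j in range(d)] for i in range(d)]
        attn = [softmax_row(r) for r in scores]
        heads.append(matmul(attn, v))
    concat = [[heads[h][i][f] for h in range(n) for f in range(F)]
              for i in range(d)]
    return matmul(concat, wo)


def elu(v, alpha=1.0):
    return v if v > 0 else alpha * (math.exp(v) - 1.0)


def _conv_same(trace, kernel):
    """Cross-correlation with same zero padding, left pad (T-1)//2."""
    T = len(kernel)
    S = len(trace)
    left = (T - 1) // 2
    padded = [0.0] * left + list(trace) + [0.0] * (T - 1 - left)
    return [sum(kernel[t] * padded[s + t] for t in range(T))
            for s in range(S)]


def _bn_eval(value, mean, var, gamma, beta, eps=1e-5):
    return (value - mean) / math.sqrt(var + eps) * gamma + beta


def _avgpool(trace, p):
    n = len(trace) // p
    return [sum(trace[i * p:(i + 1) * p]) / p for i in range(n)]


def positional_encoding_loops(d, width):
    pe = [[0.0] * width for _ in range(d)]
    for p in range(d):
        for i in range(width):
            angle = p / (10000.0 ** ((i - i % 2) / width))
            pe[p][i] = math.sin(angle) if i % 2 == 0 else math.cos(angle)
    return pe


def ertnet_forward_loops(x, params, cfg):
    """Evaluation-mode forward pass of the whole architecture for one
    epoch ``x`` = [C][S] (list of lists), returning the K logits.

    ``params`` is a dict of plain nested lists:
      temporal [F1][T]; bn1 mean/var/gamma/beta [F1];
      spatial [F1][D][C]; bn2 * [F2]; sep_depthwise [F2][Ts];
      sep_pointwise [F2][F2]; bn3 * [F2];
      per block: wq/wk/wv [n][F2][F2], wo [n*F2][F2],
      ln1/ln2 gamma/beta [F2], ff_w [F2][F2], ff_b [F2];
      head_w [F2][K], head_b [K].
    ``cfg`` needs f1, depth, f2, pool1, pool2, n_heads, n_blocks, alpha.
    """
    C = len(x)
    f1, D, F2 = cfg["f1"], cfg["depth"], cfg["f2"]
    alpha = cfg.get("alpha", 1.0)

    # 1) temporal conv (no activation) + batch norm (running stats)
    stage1 = [[_conv_same(x[c], params["temporal"][f]) for c in range(C)]
              for f in range(f1)]
    stage1 = [[[_bn_eval(v, params["bn1_mean"][f], params["bn1_var"][f],
                         params["bn1_gamma"][f], params["bn1_beta"][f])
                for v in trace] for trace in stage1[f]] for f in range(f1)]

    # 2) depthwise spatial conv collapsing channels, bn, ELU
    S = len(stage1[0][0])
    stage2 = []
    for f in range(f1):
        for j in range(D):
            trace = [sum(params["spatial"][f][j][c] * stage1[f][c][s]
                         for c in range(C)) for s in range(S)]
            stage2.append(trace)
    stage2 = [[elu(_bn_eval(v, params["bn2_mean"][m], params["bn2_var"][m],
                            params["bn2_gamma"][m], params["bn2_beta"][m]),
                   alpha)
               for v in stage2[m]] for m in range(F2)]

    # 3) average pool
    stage3 = [_avgpool(tr, cfg["pool1"]) for tr in stage2]

    # 4) separable conv (depthwise temporal then pointwise mix), bn, ELU,
    #    pool
    dw = [_conv_same(stage3[m], params["sep_depthwise"][m])
          for m in range(F2)]
    pw = [[sum(params["sep_pointwise"][g][m] * dw[m][s] for m in range(F2))
           for s in range(len(dw[0]))] for g in range(F2)]
    pw = [[elu(_bn_eval(v, params["bn3_mean"][g], params["bn3_var"][g],
                        params["bn3_gamma"][g], params["bn3_beta"][g]),
               alpha) for v in pw[g]] for g in range(F2)]
    pooled = [_avgpool(tr, cfg["pool2"]) for tr in pw]

    # 5) tokens [d][F2] + positional encoding
    d = len(pooled[0])
    tokens = [[pooled[g][s] for g in range(F2)] for s in range(d)]
    pe = positional_encoding_loops(d, F2)
    tokens = [[tokens[s][g] + pe[s][g] for g in range(F2)] for s in range(d)]

    # 6) transformer blocks
    def layer_norm(rows, gamma, beta, eps=1e-5):
        out = []
        for row in rows:
            mean = sum(row) / len(row)
            var = sum((v - mean) ** 2 for v in row) / len(row)
            out.append([(v - mean) / math.sqrt(var + eps) * gamma[i]
                        + beta[i] for i, v in enumerate(row)])
        return out

    for b in range(cfg["n_blocks"]):
        blk = params["blocks"][b]
        att = mha_loops(tokens, blk["wq"], blk["wk"], blk["wv"], blk["wo"])
        tokens = layer_norm(
            [[tokens[s][g] + att[s][g] for g in range(F2)]
             for s in range(d)], blk["ln1_gamma"], blk["ln1_beta"])
        ff = [[elu(sum(tokens[s][m] * blk["ff_w"][m][g] for m in range(F2))
                   + blk["ff_b"][g], alpha) for g in range(F2)]
              for s in range(d)]
        tokens = layer_norm(
            [[tokens[s][g] + ff[s][g] for g in range(F2)]
             for s in range(d)], blk["ln2_gamma"], blk["ln2_beta"])

    # 7) global average pooling + dense head
    gap = [sum(tokens[s][g] for s in range(d)) / d for g in range(F2)]
    K = len(params["head_b"])
    return [sum(gap[g] * params["head_w"][g][k] for g in range(F2))
            + params["head_b"][k] for k in range(K)]


def wilcoxon_enumeration(a, b):
    """Exact two-sided signed-rank p by enumerating all sign assignments."""
    diffs = [x - y for x, y in zip(a, b) if x != y]
    n = len(diffs)
    mags = sorted(abs(v) for v in diffs)
    # midranks
    ranks = []
    for v in diffs:
        m = abs(v)
        idx = [i for i, u in enumerate(mags) if u == m]
        ranks.append(sum(i + 1 for i in idx) / len(idx))
    w_plus = sum(r for v, r in zip(diffs, ranks) if v > 0)
    w_minus = sum(r for v, r in zip(diffs, ranks) if v < 0)
    lo, hi = min(w_plus, w_minus), max(w_plus, w_minus)
    count = 0
    for mask in range(2 ** n):
        w = sum(ranks[i] for i in range(n) if mask >> i & 1)
        if w <= lo + 1e-9 or w >= hi - 1e-9:
            count += 1
    return min(w_plus, w_minus), count / 2.0 ** n


def auc_pairwise(scores, labels):
    """AUC as the pairwise positive-over-negative comparison count."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))
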