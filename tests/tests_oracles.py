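"""Independent brute-force oracles shared by the unit and acceptance suites.

These deliberately re-derive results by flat enumeration rather than calling
the library's algorithms.
"""

import itertools

from mitocomp.trna_structure import DEFAULT_PARAMS, valid_pair


def oracle_breakpoints(a, b):
    """Count oriented adjacencies of circular order `a` absent from `b`,
    reading `b` in both directions (reverse reading flips strand signs)."""
    def adjacencies(order):
        out = set()
        labs = list(order.labels)
        n = len(labs)
        for reading in (labs, [(g, -s) for g, s in reversed(labs)]):
            for i in range(n):
                out.add((reading[i], reading[(i + 1) % n]))
        return out
    adj_b = adjacencies(b)
    n = len(a.labels)
    return sum(1 for i in range(n)
               if (a.labels[i], a.labels[(i + 1) % n]) not in adj_b)


def oracle_fold_pairs(seq, params=DEFAULT_PARAMS, expected_anticodon=None):
    """Exhaustive enumeration of every layout-constrained cloverleaf.

    Flat brute force over anticodon anchor, acceptor prefix length and all
    D/T stem-loop placements, maximising the lexicographic key the folder
    documents: (pairs, acceptor, -variable, -anchor, anticodon stem, D stem,
    T stem, -D start, -D loop, -T loop).  Returns the winning pair set
    (1-based) or None when no anticodon arm exists.
    """
    L = len(seq)
    gu = params.allow_gu

    def arm_options(lo, hi, smin, smax, loop_max, start_max=None):
        opts = [None]
        for start, s, ll in itertools.product(
                range(lo, hi), range(smin, smax + 1),
                range(params.loop_min, loop_max + 1)):
            if start + 2 * s + ll > hi:
                continue
            if start_max is not None and start > start_max:
                continue
            end = start + 2 * s + ll
            if all(valid_pair(seq[start + k], seq[end - 1 - k], gu)
                   for k in range(s)):
                opts.append((s, start, ll))
        return opts

    best_key, best_pairs = None, None
    for c in range(params.anticodon_min, params.anticodon_target + 1):
        arm = 2 * c + 7
        for p in range(0, L - arm + 1):
            if not all(valid_pair(seq[p + k], seq[p + arm - 1 - k], gu)
                       for k in range(c)):
                continue
            if expected_anticodon and seq[p + c + 2:p + c + 5] != expected_anticodon:
                continue
            for a in range(0, min(params.acceptor_target, L // 2) + 1):
                if a and not all(valid_pair(seq[i], seq[L - 1 - i], gu)
                                 for i in range(a)):
                    continue
                if p < a or p + arm > L - a:
                    continue
                d_opts = arm_options(a, p, params.d_min, params.d_target,
                                     params.d_loop_max)
                t_lo = p + arm
                t_opts = arm_options(t_lo, L - a, params.t_min, params.t_target,
                                     params.t_loop_max,
                                     start_max=t_lo + params.var_max)
                for d_opt, t_opt in itertools.product(d_opts, t_opts):
                    d = d_opt[0] if d_opt else 0
                    t = t_opt[0] if t_opt else 0
                    var = (t_opt[1] - t_lo) if t_opt else 0
                    key = (a + c + d + t, a, -var, -p, c, d, t,
                           -(d_opt[1] if d_opt else 0),
                           -(d_opt[2] if d_opt else 0),
                           -(t_opt[2] if t_opt else 0))
                    if best_key is None or key > best_key:
                        best_key = key
                        pairs = {(i + 1, L - i) for i in range(a)}
                        pairs |= {(p + k + 1, p + arm - k) for k in range(c)}
                        for opt in (d_opt, t_opt):
                            if opt:
                                s, st, ll = opt
                                pairs |= {(st + k + 1, st + 2 * s + ll - k)
                                          for k in range(s)}
                        best_pairs = pairs
    return best_pairs
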