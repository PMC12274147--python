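"""Independent brute-force oracles used only by the test suite.

Deliberately naive: plain Python loops over the full cross-product of paths,
scalar arithmetic from raw coefficient values.  Shares no evaluation code with
the package internals it checks.
"""

from itertools import product

import math


def logistic(z):
    return 1.0 / (1.0 + math.exp(-z))


def clip01(p):
    return min(1.0, max(0.0, p))


def shift_odds(pi, delta):
    return delta * pi / (1.0 + (delta - 1.0) * pi)


def true_mean_brute(config, delta, outcome_time):
    """Exact intervention mean for a discrete synthetic config.

    Full enumeration over baseline combinations and (l, x, y) paths; the
    terminal outcome is closed out with its conditional mean.
    """
    k = len(config.p_c)
    a, b, g = config.coef_l, config.coef_x, config.coef_y
    s = outcome_time
    total = 0.0
    for cvals in product((0, 1), repeat=k):
        wc = 1.0
        for p, v in zip(config.p_c, cvals):
            wc *= p if v else 1.0 - p
        cdot_a = sum(ci * vi for ci, vi in zip(a.c, cvals))
        cdot_b = sum(ci * vi for ci, vi in zip(b.c, cvals))
        cdot_g = sum(ci * vi for ci, vi in zip(g.c, cvals))
        # enumerate (l_t, x_t) for every wave and y_t for waves before s
        spaces = []
        for t in range(1, s + 1):
            spaces.extend([(0, 1), (0, 1)])        # l_t, x_t
            if t < s:
                spaces.append((0, 1))              # y_t
        for path in product(*spaces):
            vals = list(path)
            lprev = xprev = yprev = 0.0
            w = wc
            ey_final = None
            pos = 0
            for t in range(1, s + 1):
                l, x = vals[pos], vals[pos + 1]
                pos += 2
                pl = clip01(a.intercept + cdot_a + a.l_prev * lprev
                            + a.x_prev * xprev + a.y_prev * yprev)
                w *= pl if l else 1.0 - pl
                pi = logistic(b.intercept + cdot_b + b.l * l
                              + b.x_prev * xprev + b.y_prev * yprev)
                q = shift_odds(pi, delta)
                w *= q if x else 1.0 - q
                ey = clip01(g.intercept + g.x * x + cdot_g + g.l * l
                            + g.x_prev * xprev + g.y_prev * yprev + g.x_l * x * l)
                if t == s:
                    ey_final = ey
                else:
                    y = vals[pos]
                    pos += 1
                    w *= ey if y else 1.0 - ey
                    lprev, xprev, yprev = float(l), float(x), float(y)
            total += w * ey_final
    return total


def fitted_mean_brute(panel, system_fit, ps_fits, delta, outcome_time):
    """Path sum with *fitted* models substituted, averaging over observed C rows.

    Evaluates every linear predictor by explicit dot products over the fitted
    term lists (terms resolved by name against a per-path value dict).
    """
    schema = panel.schema
    s = outcome_time
    fits = {f.t: f for f in ps_fits}

    def linpred(design, coef, vals):
        out = 0.0
        for name, c in zip(design.term_names, coef):
            if name == "const":
                out += c
            else:
                prod = 1.0
                for col in name.split(":"):
                    prod *= vals[col]
                out += c * prod
        return out

    total = 0.0
    n = panel.n
    for i in range(n):
        base = {c: float(panel.data.iloc[i][c]) for c in schema.C}
        spaces = []
        for t in range(1, s + 1):
            spaces.extend([(0, 1), (0, 1)])
            if t < s:
                spaces.append((0, 1))
        acc = 0.0
        for path in product(*spaces):
            vals = dict(base)
            w = 1.0
            pos = 0
            ey_final = None
            for t in range(1, s + 1):
                lcol = schema.L[t][0]
                leq = system_fit.equations[lcol]
                pl = clip01(linpred(leq.design, leq.coef, vals))
                l = path[pos]
                vals[lcol] = float(l)
                w *= pl if l else 1.0 - pl
                pf = fits[t]
                pi = logistic(linpred(pf.design, pf.coef, vals))
                q = shift_odds(pi, delta)
                x = path[pos + 1]
                vals[schema.X[t]] = float(x)
                w *= q if x else 1.0 - q
                pos += 2
                yeq = system_fit.equations[schema.Y[t]]
                ey = clip01(linpred(yeq.design, yeq.coef, vals))
                if t == s:
                    ey_final = ey
                else:
                    y = path[pos]
                    pos += 1
                    vals[schema.Y[t]] = float(y)
                    w *= ey if y else 1.0 - ey
            acc += w * ey_final
        total += acc
    return total / n
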