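"""Independent brute-force oracles for the propagation equations.

Everything here is pure-Python dict/loop code deliberately sharing nothing
with the pandas pipeline: consumption, import shares, export composition,
the global score, the import-side and consumption-side scores, and
consumption-weighted aggregation are all expanded literally from their
definitions.  ``exact=True`` runs the whole expansion in rational
arithmetic (``fractions.Fraction``), which is how exactness claims are
verified without floating-point slack.
"""

from __future__ import annotations

from fractions import Fraction

FIXED_PPC = {"proportional": None, "gephart": 0.365, "guillen": 0.74}


def brute_force_fmi_c(balance, trade, cf_map, fmi_table, derivations,
                      exact=False):
    """Triple-loop expansion of the consumption-score equations.

    Parameters mirror the generator's raw tables: ``balance`` and ``trade``
    are DataFrames, ``cf_map`` maps product codes to conversion factors,
    ``fmi_table`` is the (assembled) score table.  Returns
    ``{(country, group_or_'AGGREGATE', derivation): fmi_c}``.
    """
    num = (lambda x: Fraction(x)) if exact else float
    zero = Fraction(0) if exact else 0.0

    score = {c: num(v) for c, v in zip(fmi_table["country_id"],
                                       fmi_table["fmi"])}

    P, I, E, C = {}, {}, {}, {}
    for r in balance.itertuples(index=False):
        k = (r.country_id, r.product_group)
        p, i, e = num(r.production_t), num(r.imports_t), num(r.exports_t)
        P[k] = P.get(k, zero) + p
        I[k] = I.get(k, zero) + i
        E[k] = E.get(k, zero) + e
        C[k] = C.get(k, zero) + max(p + i - e, zero)

    groups = sorted({g for (_c, g) in P})
    countries = sorted({c for (c, _g) in P})

    # live-weight bilateral imports
    m = {}
    for r in trade.itertuples(index=False):
        if not r.is_food or r.direction != "import":
            continue
        g = cf_map["groups"][r.product_code]
        w = num(r.product_weight_t) * num(cf_map["cf"][r.product_code])
        k = (r.reporter_id, g)
        m.setdefault(k, {})
        m[k][r.partner_id] = m[k].get(r.partner_id, zero) + w

    glbl = {}
    for g in groups:
        tot = sum(P[(c, g)] for c in countries if (c, g) in P)
        glbl[g] = sum(P[(c, g)] * score[c] for c in countries
                      if (c, g) in P) / tot if tot > zero else None

    def ppe(j, g):
        denom = P.get((j, g), zero) + I.get((j, g), zero)
        if denom == zero:
            return None
        return P[(j, g)] / denom

    def fmi_i(r, g):
        flows = m.get((r, g))
        if not flows:
            return None
        tot = sum(flows.values())
        acc = zero
        for j, w in flows.items():
            pe = ppe(j, g)
            if pe is None:
                pe = zero  # no export basis: treat as fully re-exported
            acc += (w / tot) * (pe * score[j] + (1 - pe) * glbl[g])
        return acc

    out = {}
    for name in derivations:
        fixed = FIXED_PPC[name]
        for c in countries:
            wsum, fsum = zero, zero
            for g in groups:
                k = (c, g)
                basis = P.get(k, zero) + I.get(k, zero)
                if basis == zero:
                    continue
                if I.get(k, zero) == zero:
                    ppc = num(1.0)
                elif fixed is None:
                    ppc = P[k] / basis
                else:
                    ppc = num(fixed)
                imp = fmi_i(c, g)
                if ppc == 1:
                    val = score[c]
                elif imp is None:
                    val = ppc * score[c] + (1 - ppc) * glbl[g]
                else:
                    val = ppc * score[c] + (1 - ppc) * imp
                out[(c, g, name)] = val
                wsum += C[k]
                fsum += C[k] * val
            if wsum > zero:
                out[(c, "AGGREGATE", name)] = fsum / wsum
    return out


def cf_map_from_world(world):
    """Exact-lookup conversion map for a synthetic world's codes."""
    cf = dict(zip(world.conversion_factors["match_key"],
                  world.conversion_factors["cf"]))
    cf.pop("*", None)
    return {"cf": cf, "groups": world.product_group_mapping}


def normal_equations_ols(x, y):
    """Closed-form simple OLS (slope, intercept, r2) via normal equations —
    independent of the statsmodels fits it checks."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxx = sum(v * v for v in x)
    sxy = sum(a * b for a, b in zip(x, y))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    ybar = sy / n
    ss_res = sum((yi - (intercept + slope * xi)) ** 2
                 for xi, yi in zip(x, y))
    ss_tot = sum((yi - ybar) ** 2 for yi in y)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return slope, intercept, r2
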