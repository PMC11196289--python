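"""Independent brute-force transcription of the prediction equations.

Used only as a cross-check oracle in tests.  Everything here is written
directly from the printed equations in terms of primitive floats and
dicts, sharing no code with the package (natural logs are used where the
package uses log10, etc.).  Do not import the package here.
"""
import math

BW = 70.0  # kg


# --- ionization -----------------------------------------------------------

def frac_ionized_base(pka, ph):
    return 1.0 / (1.0 + math.exp(math.log(10.0) * (ph - pka)))


# --- Oie-Tozer ------------------------------------------------------------

def oracle_fut(logp, pka, fup):
    fi = 0.0 if pka is None else frac_ionized_base(pka, 7.4)
    rhs = 0.0080 - 0.2294 * logp - 0.9311 * fi + 0.8885 * (math.log(fup) / math.log(10.0))
    return math.exp(math.log(10.0) * rhs)


def oracle_oie_tozer(logp, pka, fup):
    fut = oracle_fut(logp, pka, fup)
    per_kg = 0.0436 + fup * 0.151 + 1.4 * 0.0436 * (1.0 - fup) + 0.38 * fup / fut
    return BW * per_kg


# --- tissue-composition partition coefficient -----------------------------

def oracle_kpu(p, fup, pka, tissue):
    """tissue: dict with f_nl, f_np, f_ew, f_iw, albumin_ratio, lipoprotein_ratio.
    p is the partition coefficient 10**logP (already exponentiated)."""
    if pka is None:
        x = y = 1.0
        r = tissue["lipoprotein_ratio"]
    else:
        x = 1.0 + 10.0 ** (pka - 7.22)
        y = 1.0 + 10.0 ** (pka - 7.4)
        r = tissue["albumin_ratio"]
    term = x * tissue["f_iw"] / y + tissue["f_ew"]
    term += (p * tissue["f_nl"] + (0.3 * p + 0.7) * tissue["f_np"]) / y
    term += (1.0 / fup - 1.0 - (p * 0.0023 + (0.3 * p + 0.7) * 0.0013)) * r
    return term


def oracle_rr_tissue(logp, pka, fup, tissues, adipose_oil=False):
    vuss = 3.5 / fup
    for t in tissues:
        p = 10.0 ** logp
        if adipose_oil and t["tissue"] == "adipose":
            p = 10.0 ** (1.099 * logp - 1.31)
        vuss += t["volume"] * oracle_kpu(p, fup, pka, t)
    return vuss * fup


def oracle_rr_muscle(logp, pka, fup, tissues):
    muscle = [t for t in tissues if t["tissue"] == "muscle"][0]
    total_v = sum(t["volume"] for t in tissues)
    vuss = 3.5 / fup + total_v * oracle_kpu(10.0 ** logp, fup, pka, muscle)
    return vuss * fup


# --- adjusted-fup perfusion-limited method --------------------------------

def oracle_adjusted_fup(logp, pka, fup, bpr, tissues, hct=0.45,
                        ratio=(0.0023 + 0.0013) / 0.945, adipose_oil=False):
    logd = logp if pka is None else logp - math.log10(1.0 + 10.0 ** (pka - 7.4))
    fup_adj = 1.0 / (10.0 ** logd * ratio + 1.0 + (1.0 - fup) / fup)
    ep = max((bpr - (1.0 - hct)) / hct, 0.0)
    v_e = hct / (1.0 - hct) * 3.5
    vdss = 3.5 + v_e * ep
    for t in tissues:
        p = 10.0 ** logp
        if adipose_oil and t["tissue"] == "adipose":
            p = 10.0 ** (1.099 * logp - 1.31)
        vdss += t["volume"] * oracle_kpu(p, fup, pka, t) * fup_adj
    return vdss


# --- microsomal-partitioning method ---------------------------------------

def oracle_log_lkl(logp, pka_b, hbd, hba, n_so, n_no2, dipole, c, pka_a=None):
    group = c["e"] * n_so + c["f"] * n_no2
    s = 10.0 ** (c["const1"] + c["a1"] * logp + c["d1"] * dipole + group)
    corr = 0.0
    if pka_b is not None:
        s += 10.0 ** (c["const2"] + c["a2"] * logp + c["b2"] * hba
                      + c["c2"] * hbd + group + pka_b - 7.4)
        corr -= math.log10(1.0 + 10.0 ** (pka_b - 7.4))
    if pka_a is not None:
        s += 10.0 ** (c["const3"] + c["b3"] * hba + group + pka_a - 7.4)
        corr -= math.log10(1.0 + 10.0 ** (7.4 - pka_a))
    return math.log10(s) + corr


def oracle_korzekwa_nagar(logp, pka_b, fup, hbd, hba, n_so, n_no2, dipole, c):
    lkl = 10.0 ** oracle_log_lkl(logp, pka_b, hbd, hba, n_so, n_no2, dipole, c)
    fum = 1.0 / (1.0 + lkl)
    per_kg = (0.043 + 0.557 * fup + 0.557 * 0.116 * (1.0 - fup)
              + fup * (20.0 * (1.0 - fum) / fum + 0.76))
    return BW * per_kg


# --- blood:plasma-ratio tissue-composition method -------------------------

def oracle_tcm_new(logp, bpr):
    logp_oil = 1.099 * logp - 1.31
    num = 0.48 + 0.22 + 10.0 ** logp_oil * (0.149 + 0.00075 / 5.0)
    den = 0.29 + 0.53 + 10.0 ** logp * (0.004 + 0.00075)
    return BW * (bpr * num / den + 0.04)


# --- error metrics (natural-log route) ------------------------------------

def oracle_afe(folds):
    return math.exp(sum(math.log(f) for f in folds) / len(folds))


def oracle_aafe(folds):
    return math.exp(sum(abs(math.log(f)) for f in folds) / len(folds))
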