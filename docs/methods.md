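# Methods

This note documents the models implemented in `vdsspred`, their
assumptions, the defaults that matter, and the numerical and design
choices made where the published descriptions leave room.

## Scope and data

All methods predict the steady-state volume of distribution (VDss, L) of
a neutral or weakly basic drug in a 70-kg human from physicochemical
inputs: logP (by source: in-silico `admet`, `literature`, chromatographic
`hplc`), basic pKa, fraction unbound in plasma (fup), blood:plasma
concentration ratio (BPR), and — for the microsomal method — H-bond
counts, SO/NO₂ counts and dipole moment.  Moderate-to-strong bases
(positively charged at plasma pH) are out of scope: the acidic-
phospholipid-binding form of the partition equation is not implemented
because every supported drug class uses the neutral/weak-base form.

The packaged drug table carries the four reference antifungals with
observed human VDss from IV studies (107, 800, 294, 304 L).  Two source
conflicts are resolved as follows: isavuconazole fup is 0.01 (the value
tabulated with the drug's other parameters; a prose mention of "0.1"
elsewhere is treated as a typo — the group error statistics only
reproduce with 0.01), and griseofulvin in-silico logP is 2.511 (tabulated
twice; a prose mention of 2.411 is likewise treated as a typo).

The packaged tissue table lists residual-blood-adjusted fractional
volumes for 13 rat tissues with absolute volumes for a 70-kg human
(summing to 66.87 L) and tissue:plasma albumin and lipoprotein ratios.
The adipose row uses the canonical composition (f_NL 0.853, f_NP 0.0016,
f_EW 0.135, f_IW 0.017): adipose is mostly neutral lipid, which also
means its composition fractions sum to 1.0066 — the validation bound on
the composition sum is therefore 1.01, not 1.  The table is overridable
via `load_tissue_table(path)`.

## The six methods

**Physiological binding model (`oie_tozer`).**  VDss/kg = V_p + fup·V_e +
R_e/i·V_p(1−fup) + V_r·fup/fut with V_p 0.0436, V_e 0.151, R_e/i 1.4,
V_r 0.38 L/kg.  The tissue fraction unbound comes from the regression
log fut = 0.0080 − 0.2294·logP − 0.9311·f_i(7.4) + 0.8885·log fup, with
the ionized fraction from Henderson–Hasselbalch.  The regression can
extrapolate above fut = 1 at very low logP; this warns rather than
errors so sweeps can traverse the grid.  fut is assumed identical in all
tissues.

**Tissue-composition partition model (`rr_tissue`, `rr_muscle`).**  Kpu
per tissue as in the README formula; the unbound volume Vuss =
V_p/fup + Σ V_i·Kpu_i (V_p = 3.5 L) is converted exactly by VDss =
Vuss·fup.  The muscle-only variant applies muscle Kpu to the whole
66.87 L tissue volume.  The protein-binding term can be negative for
very lipophilic drugs; a non-positive total Kpu raises (physically
inconsistent input).  The vegetable-oil partition coefficient
(logP_oil = 1.099·logP − 1.31) may be used for adipose via
`adipose_partition="oil"`; the default is octanol.

**Perfusion-limited model with adjusted fup (`adjusted_fup`).**  Kp =
Kpu·fup_adj, where fup_adj = 1/(10^logD(7.4)·(V_lipid/V_water) + 1 +
(1−fup)/fup) corrects fup for partitioning into plasma lipid.  VDss =
V_p + V_e·E:P + Σ V_t·Kp_t with all tissue extraction ratios set to 0
(no extraction data are published for this use).  Defaults chosen here
because they are not published with the method: V_lipid/V_water =
(0.0023 + 0.0013)/0.945 (plasma neutral-lipid plus phospholipid fraction
over plasma water); erythrocyte volume V_e = Hct/(1−Hct)·V_p with
hematocrit 0.45; E:P = (BPR − (1−Hct))/Hct, clipped at zero with a
warning; logD from the monoprotic-base Henderson–Hasselbalch correction
(logD = logP for neutrals).  All three are configurable.  The original
software implementation of this approach uses proprietary physiology
tables and plasma-lipid constants, so printed values for it are matched
only at the fold-band level; its per-tissue volumes here reuse the
packaged 13-tissue table (a documented approximation).  Notably, the
published "within twofold for itraconazole" behaviour at literature logP
is reproduced under the oil-adipose option (fold ≈ 0.70) but not under
octanol (fold ≈ 2.6).

**Microsomal-partitioning model (`korzekwa_nagar`).**  fum from the
three-exponential regression log(L·K_L) = log(10^E1 + 10^E2 + 10^E3) −
log(1+10^(pKa,b−7.4)) − log(1+10^(7.4−pKa,a)), where E1 is the neutral
term (logP, dipole, SO/NO₂), E2 the cation term (shifted by pKa,b − 7.4)
and E3 the anion term (shifted by pKa,a − 7.4).  A species whose group is
absent contributes zero to the sum and a zero correction.  VDss/kg =
0.043 + 0.557·fup + 0.557·0.116·(1−fup) + fup·(20·(1−fum)/fum + 0.76).
The regression constants are distributed in an external supplement and
are **not bundled**: the packaged `kn_constants.yaml` holds nulls and the
method is unavailable (not an error) until they are supplied.  A
synthetic, clearly-labelled constants file with plausible signs ships
for exercising the pipeline in tests.  Predictions for drugs with
fup < 0.005 warn: the regression was developed excluding them, and the
fup·(1−fum)/fum term makes the model very sensitive there.

**Blood:plasma-ratio tissue-composition model (`tcm_new`).**  VDss/kg =
BPR·(0.48 + 0.22 + 10^logP_oil·(0.149 + 0.00075/5)) / (0.29 + 0.53 +
10^logP·(0.004 + 0.00075)) + 0.04, with logP_oil from the affine oil
map.  The numerator's NLP/5 divisor and the shared 0.00075 lipoprotein
fraction are implemented exactly as published.  This is the only method
that does not use fup.

## Sensitivity sweeps and error metrics

Sweeps walk an inclusive logP grid built by integer stepping (no
floating accumulation), default step 0.5, and record per grid point each
method's VDss plus the logP-sensitive intermediates (fut/fup ratio,
adipose Kp, muscle Kp).  A method failure at a grid point becomes a
flagged row, not a crash.

Fold error is predicted/observed; AFE and AAFE are base-10 geometric
means of the fold errors and of their absolute log10 values.  Summaries
are produced per logP source, per drug, and combined; with equal group
sizes the combined AFE equals the geometric mean of the per-source AFEs
(used as a cross-check).  Text tables round to two decimals; CSVs keep
full precision.  Fold errors are always computed against the literature
observed VDss, not the NCA/compartmental re-estimates.

Known residuals against the published statistics, with the packaged
inputs: the tissue-specific combined AFE computes to 23.6 (octanol
adipose) or 5.8 (oil adipose) against a printed 9.09 — the oil setting
is the closer of the two, and the originating workbook's exact choices
are not recoverable; the printed AAFE values of several mixed-sign
groups equal their AFEs, which is arithmetically impossible (AAFE ≥
max(AFE, 1/AFE) with equality only when all folds lie on one side of 1)
and is treated as errata; the muscle-only literature-logP fold error for
isavuconazole computes to 0.12 (a printed 0.16 elsewhere is inconsistent
with the group AFE of 1.56, which 0.12 reproduces); and the
physiological model's AFEs land within 0.1 of the printed values (e.g.
1.16 vs 1.21 for griseofulvin), consistent with rounded intermediates in
the original calculation.  An ordering worth noting: the muscle-only
prediction exceeds the adjusted-fup prediction at chromatographic logP
only for the low-fup drugs (itraconazole, posaconazole); for fup ≥ 0.01
the adjusted method's full-tissue sum (adipose-dominated) is larger.

## NCA and compartmental analysis

NCA uses the linear-up/log-down trapezoid (the published workflow does
not state a quadrature; this is the field default), back-extrapolates
log-linearly to t = 0 for bolus profiles, and extrapolates the tail with
the terminal rate constant fitted through the last three points
(configurable).  A non-declining terminal phase is an error.  VDss =
MRT·CL.

Compartmental fits parameterise the mammillary model by log micro
constants (V1, k10, k12, k21, k13, k31), evaluate the bolus solution by
eigendecomposition of the rate matrix, and minimise Σ((y−ŷ)/ŷ)² — the
1/ŷ² weighting of the original workflow.  Initialisation is
deterministic: curve stripping yields macro exponentials that are
converted exactly to micro constants, plus two fixed-factor restarts.
AIC = m·ln(WSS/m) + 2p with p = 2n; ties select the smaller model.
Compartment volumes are V1 and V1·k1i/ki1, and VDss is their sum.

The published per-drug NCA/compartmental values (99.9–578.9 L) derive
from digitized literature profiles that are not distributed, so they are
not test targets; the pipeline is validated by parameter recovery on
simulated profiles instead (noiseless two-compartment fits recover the
analytic Vss to 1e-4 relative; with 5 % multiplicative noise the median
recovery error over 50 replicates stays under 10 %).

## Synthetic data

The drug generator spans the study regime — logP 2–7 (three draws per
drug, rank-ordered across the sources to mirror the in-silico <
literature < chromatographic ordering seen in practice), weak bases with
pKa 3–5 and a 0.25 neutral probability, fup log-uniform over 0.002–0.2
(the regime spans two orders of magnitude), BPR 0.6–0.8, HBD 0–5, HBA
2–12, SO/NO₂ 0–2, dipole 1–15 D.  Profiles come from the closed-form
bolus solution on a 0.083–72 h schedule with multiplicative log-normal
noise (mean-one parameterisation).  Everything is bit-reproducible under
a seed.

What the generators do not emulate: correlations between descriptors and
logP, assay error in fup/BPR themselves, oral/infusion kinetics, and
inter-subject variability (profiles represent a study-mean curve).
Passing tests therefore demonstrate internal correctness of the
equations and pipelines, not field accuracy on new chemistry.

## Problem sizes

The test suite uses 100 synthetic drugs for oracle equivalence, 10 000
for the generator's binomial check, and 50 noisy replicates for the
recovery study; these sizes make every statistical margin comfortable
while keeping the whole suite around a few seconds.
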