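# Packaged reference tables

`reference_lsmeans.csv` — dose least-squares means, SEM and p-values from a
91-d lubabegron (selective β-modulator) feeding trial in environmentally
monitored cattle-pen enclosures (4 doses × 2 sexes × 3 cycles, pooled over
sex).  One row per response variable; columns:

- `variable` — response identifier (`nh3_g_per_animal_d0_91` is the 91-d
  cumulative NH3 emission in g/animal; `..._per_kg_bw`/`..._per_kg_hcw` are
  standardized by unshrunk final BW and by HCW; `d0_7` etc. are interim
  intervals).
- `dose_0, dose_1_38, dose_5_5, dose_22` — LSMeans at 0, 1.38, 5.5 and
  22.0 mg·kg⁻¹ DM.
- `sem` — standard error of a treatment mean (n = 6 pens).
- `p_interaction`, `p_dose` — dose × sex interaction and dose main-effect
  F-test p-values.
- `p_vs_con_*` — planned pairwise contrasts of each dose against control
  (empty when the F-test did not license contrasts).  Values reported in the
  source as "<0.001" are stored as their upper bound 0.001; downstream logic
  only compares them with 0.05.

These numbers serve as fixture inputs for the worked-example calculators and
for the dose–response selection procedure; they are not outputs of this
package.
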