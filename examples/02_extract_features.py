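"""Extract the 105-feature radiomic vector from one subject's CMP phase.

Prints the feature-family sizes (18 first-order + 13 shape + 23 GLCM +
16 GLRLM + 16 GLSZM + 14 GLDM + 5 NGTDM = 105), a few representative
values, and the length of the 4-phase ALL-P concatenation (420).
"""

from rcc_radiomics import CohortConfig, combine_phases, extract_single_phase, generate_cohort

cfg = CohortConfig(counts={"ccRCC": 1, "pRCC": 0, "cRCC": 0}, shape=(32, 32, 32), seed=3)
(subject,) = generate_cohort(cfg)

vecs = {}
for phase in ("NCP", "CMP", "NP", "EP"):
    vol = subject.volumes[phase]
    vecs[phase] = extract_single_phase(vol.voxels, subject.masks[1].voxels, vol.spacing)

cmp_vec = vecs["CMP"]
print(f"single-phase vector length: {len(cmp_vec)}")
for fam in ("fo", "shape", "glcm", "glrlm", "glszm", "gldm", "ngtdm"):
    n = sum(name.startswith(fam + "_") for name in cmp_vec.index)
    print(f"  {fam:6s}: {n}")
print("\nselected CMP features:")
for name in ("fo_mean", "fo_entropy", "shape_sphericity", "glcm_contrast",
             "ngtdm_coarseness"):
    print(f"  {name:22s} {cmp_vec[name]:.4f}")
allp = combine_phases(vecs)
print(f"\nALL-P concatenation: {len(allp)} features "
      f"(first: {allp.index[0]}, last: {allp.index[-1]})")
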