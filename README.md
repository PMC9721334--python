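# fibrilsaxs

Cross-sectional structure of fibrils from small-angle X-ray scattering of
disoriented samples — in solution, in gels, or embedded in fixed-tissue thin
sections probed by a scanning microbeam.

## The problem

Amyloid and other cross-β fibrils are, at SAXS resolution, very long rods of
unknown (often heterogeneous) length. Conventional solution-SAXS analysis —
the pair distribution function P(r) with a finite maximum dimension — is
poorly suited to them: the maximum vector length is dominated by the fibril
length (or, in tissue, by fibril–matrix correlations) and is extremely
sensitive to the smallest measurable q. This package implements the
alternative that fiber-diffraction theory suggests:

1. For fibrils whose axial repeat c is short (cross-β: c ≈ 4.7 Å, first
   layer plane at q = 2π/c ≈ 1.34 Å⁻¹), all small-angle intensity is
   equatorial, and the equatorial intensity of the disoriented sample is
   recovered by a geometric correction ≈ q:  I_e(q) ≈ q · I(q).
2. The **cross-section PDF** follows from the 2D Hankel pair

       P_c(r) = (r / 2π) ∫ q I_e(q) J₀(qr) dq,    I_e(q) = 2π ∫ P_c(r) J₀(qr) dr

   and the **cross-section correlation function** a_c(r) = P_c(r)/r. Its
   decay to zero estimates the fibril diameter, independent of length; its
   behaviour beyond the diameter reports on the fibril's microenvironment
   (packing of neighbours, density of the surrounding matrix — including
   negative correlation where local density falls below the average).
3. In scanned tissue sections, fibril-rich lesions are located by mapping
   the sharp cross-β reflection at q ≈ 1.34 Å⁻¹, and the non-fibrillar
   scattering is removed by the two-reference subtraction
   I = (I_l − I_b) − a·(I_t − I_b), with the tissue scale a fitted at
   1.6 < q < 2.0 Å⁻¹ where fibrillar scattering is weak.

The package provides forward models (solid cylinders via
F(q_x, Z) = V·[2J₁(q_x R)/(q_x R)]·sinc(Z h/2), atomic models via the Debye
formula, stacked-layer fibrils), the equatorial recovery, direct and
regularised indirect Fourier transforms in both spherical and cross-section
geometry, the full scan-grid processing chain (masking, azimuthal
averaging, SAXS/WAXS merging, heat maps, background subtraction), and
synthetic generators for every input — so the entire pipeline is testable
against known ground truth.

## Worked example

```python
import numpy as np
from fibrilsaxs import (CylinderSpec, cross_section_workflow,
                        equatorial_from_isotropic, first_zero_crossing,
                        isotropic_cylinder_intensity, check_equatorial_validity)

# fibrils modelled as solid cylinders, 35 A radius, 1000 A long
q = np.linspace(0.004, 0.3, 600)
cylinder = CylinderSpec(radius=35.0, length=1000.0)

verdict = check_equatorial_validity(axial_repeat=4.7, q_max=q[-1])
print(f"equatorial recovery: {verdict.status} "
      f"(first layer plane at {verdict.first_layer_q:.2f} 1/A)")

isotropic = isotropic_cylinder_intensity(q, cylinder)
equatorial = equatorial_from_isotropic(isotropic)
p_c, a_c = cross_section_workflow(equatorial, d_max=150.0)
diameter = first_zero_crossing(a_c, r_min_search=5.0)
print(f"a_c crosses zero at {diameter:.1f} A  (true diameter {cylinder.diameter:.0f} A)")
```

prints

```
equatorial recovery: valid (first layer plane at 1.34 1/A)
a_c crosses zero at 70.9 A  (true diameter 70 A)
```

The first line confirms that for a 4.7 Å axial repeat the whole measured
window (q ≤ 0.3 Å⁻¹) lies below the first layer plane, so the ∝q equatorial
recovery is legitimate. The second line is the diameter estimate: the
normalised cross-section correlation function of the recovered equatorial
intensity crosses zero at 70.9 Å, within ~1 Å of the true 70 Å diameter —
the residual offset comes from the band-limited window and the small-q
approximation in the ∝q correction.

The same analysis is available from the shell:

```sh
fibrilsaxs simulate cylinder --radius 35 --length 1000 --out cyl.dat
fibrilsaxs xsection cyl.dat --out-prefix cyl
# a_c first zero crossing: 70.9 A (fibril diameter estimate)
```

and the scanning workflow (`fibrilsaxs simulate scan`, `fibrilsaxs scan
heatmap`, `fibrilsaxs scan subtract`) runs heat-map lesion location and
two-reference background subtraction on a scan directory.

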