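# Synthetic chromophore absorption basis spectra for two-layer skin modeling.
# Units: mm^-1 at 100% volume concentration of the chromophore carrier.
#   eps_melanin — melanosome-like power law, 49.6*(550/lambda)^3.33 mm^-1
#   eps_oxy     — whole oxygenated blood (~150 g/L hemoglobin), smooth
#                 analytic stand-in with the standard 542/577 nm double peak
#   eps_deoxy   — whole deoxygenated blood, single 556 nm peak, red-region
#                 absorption above the oxygenated curve
# These columns are smooth synthetic approximations carrying the standard
# spectral features (peak positions, isosbestic crossings near 500/548/570/
# 586 nm); they are not digitized measurement data.  The pipeline treats the
# table as an exchangeable input: swap this file to model other absorbers.
wavelength_nm,eps_melanin,eps_oxy,eps_deoxy
450,96.759,33.70,55.40
460,89.930,23.90,32.20
470,83.715,17.80,20.40
480,78.047,14.30,14.50
490,72.868,12.70,12.10
500,68.127,11.20,11.20
510,63.779,10.80,13.80
520,59.786,13.00,16.60
530,56.111,21.40,20.90
540,52.725,28.60,25.00
550,49.600,23.10,28.00
560,46.711,17.50,28.60
570,44.038,24.10,24.20
580,41.560,26.90,19.90
590,39.260,7.90,15.20
600,37.123,1.70,7.90
610,35.135,0.81,5.10
620,33.283,0.51,3.50
630,31.556,0.33,2.80
640,29.944,0.24,2.30
650,28.437,0.20,2.00
660,27.028,0.17,1.70
670,25.708,0.16,1.50
680,24.470,0.15,1.30
690,23.309,0.15,1.20
700,22.218,0.16,1.00
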