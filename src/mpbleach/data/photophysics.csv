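# Molecular multiphoton-photobleaching parameters of red fluorescent proteins,
# per (protein, wavelength): two-photon absorption cross section sigma2 (GM),
# quadratic-regime reaction yield phi_12 (phi1 or phim), the cross-section
# product sigma_mn*sigma_nc (cm^4) and its factors (cm^2), the three-photon
# product sigma_mn*phi_n (cm^2) and its factors, fluorescence quantum yield
# phi_F, and vertical electron detachment energy VDE (eV).
# n_photons is the diagnosed number of photons driving bleaching at that
# wavelength (a range where the mechanism switches with power).
protein,lambda_nm,n_photons,sigma2_GM,phi_12,sigma_mn_sigma_nc_cm4,sigma_mn_cm2,sigma_nc_cm2,sigma_mn_phi_n_cm2,phi_n,phi_F,vde_eV
mCherry,1100,2,24,1.6e-5,,,,,,0.24,5.52
mCherry,1000,2,6.2,1.0e-4,,,,,,0.24,5.52
mCherry,800,2-4,22,1.0e-4,5.0e-36,3.7e-17,1.3e-19,,,0.24,5.52
mCherry,780,2-4,42,8.5e-5,1.7e-35,5.0e-17,3.4e-19,,,0.24,5.52
mCherry,760,2-4,71,1.0e-4,3.3e-35,8.8e-17,7.3e-19,,,0.24,5.52
mPlum,790,2-4,43,1.3e-4,1.6e-35,,,,,0.13,5.61
jREX-GECO1,1100,2,7.9,2.1e-4,,,,,,0.21,
jREX-GECO1,1000,2,25,5.7e-5,,,,,,0.21,
jREX-GECO1,950,2,34,5.0e-5,,,,,,0.21,
jREX-GECO1,925,3,38,,,,,1.2e-20,,0.21,
jREX-GECO1,900,3,35,,,,,2.0e-20,,0.21,
jREX-GECO1,800,3,8.8,,,,,7.7e-21,,0.21,
jREX-GECO1,780,3,6.5,,,,,1.5e-20,,0.21,
jREX-GECO1,760,3,8.7,,,1.4e-17,,3.0e-20,2.2e-3,0.21,
tdTomato,1100,4,80,,2.3e-36,,,,,0.72,
tdTomato,1000,2-8,56,3.7e-5,,,,,,0.72,
tdTomato,970,2-10,42,1.6e-5,,,,,,0.72,
tdTomato,860,5,22,,,,,,,0.72,
tdTomato,820,4,3.2,,4.3e-36,,,,,0.72,
tdTomato,780,4,8.7,,1.6e-35,4.3e-17,3.8e-20,,,0.72,
tdTomato,760,4,31,,,,4.8e-19,,,0.72,
DsRed2,790,5,,,,,,,,,7.24
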