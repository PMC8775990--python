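# Threshold operating points of mCherry: the molecular combination
# sqrt(phi_m / (sigma_mn sigma_nc)) (cm^-2), the squared beam waist at each
# wavelength (cm^2), and the predicted / observed threshold powers (mW) with
# the corresponding peak photon fluxes (photons/cm^2/s).
lambda_nm,sqrt_phi_over_product_per_cm2,w0_sq_cm2,Pstar_predicted_mW,I0star_predicted,Pstar_observed_mW,I0star_observed
760,1.7e15,1.32e-7,26,3.6e28,19,2.6e28
780,2.2e15,1.37e-7,34,3.9e28,28,3.2e28
800,4.5e15,1.43e-7,68,5.4e28,61,4.8e28
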