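# pbisim bundled reference material table.
# Units: energy_keV in keV, delta dimensionless, mu_over_rho_cm2_g in cm^2/g,
# density_g_cm3 in g/cm^3.  Linear attenuation is computed as mu = (mu/rho)*rho.
# delta values are anchored at 60 keV (airway-scenario decrements for air,
# muscle and lung parenchyma; electron-density estimates for aluminum and
# CdTe) and extended with the far-from-edge 1/E^2 scaling.
# mu/rho values are reference data taken from standard photon mass-attenuation
# compilations (dry air, ICRU-44 skeletal muscle, elemental Al); the CdTe rows
# are approximate and restricted to energies above both K edges.  The CdTe and
# aluminum entries exist for filtration/metadata, not as imaged tissues.
material,density_g_cm3,energy_keV,delta,mu_over_rho_cm2_g,vacuum_like
air,0.0012,10,2.4876e-09,5.120,False
air,0.0012,15,1.1056e-09,1.614,False
air,0.0012,20,6.219e-10,0.7779,False
air,0.0012,30,2.764e-10,0.3538,False
air,0.0012,40,1.554750e-10,0.2485,False
air,0.0012,50,9.9504e-11,0.2080,False
air,0.0012,60,6.91e-11,0.1875,False
air,0.0012,80,3.886875e-11,0.1662,False
air,0.0012,100,2.4876e-11,0.1541,False
air,0.0012,150,1.1056e-11,0.1356,False
muscle,1.05,10,2.3976e-06,5.356,False
muscle,1.05,15,1.0656e-06,1.693,False
muscle,1.05,20,5.994e-07,0.8205,False
muscle,1.05,30,2.664e-07,0.3783,False
muscle,1.05,40,1.4985e-07,0.2685,False
muscle,1.05,50,9.5904e-08,0.2262,False
muscle,1.05,60,6.66e-08,0.2048,False
muscle,1.05,80,3.74625e-08,0.1823,False
muscle,1.05,100,2.3976e-08,0.1693,False
muscle,1.05,150,1.0656e-08,0.1492,False
lung_parenchyma,0.53,10,1.2132e-06,5.356,False
lung_parenchyma,0.53,15,5.392e-07,1.693,False
lung_parenchyma,0.53,20,3.033e-07,0.8205,False
lung_parenchyma,0.53,30,1.348e-07,0.3783,False
lung_parenchyma,0.53,40,7.5825e-08,0.2685,False
lung_parenchyma,0.53,50,4.8528e-08,0.2262,False
lung_parenchyma,0.53,60,3.37e-08,0.2048,False
lung_parenchyma,0.53,80,1.895625e-08,0.1823,False
lung_parenchyma,0.53,100,1.2132e-08,0.1693,False
lung_parenchyma,0.53,150,5.392e-09,0.1492,False
aluminum,2.699,10,5.4e-06,26.23,False
aluminum,2.699,15,2.4e-06,7.955,False
aluminum,2.699,20,1.35e-06,3.441,False
aluminum,2.699,30,6.0e-07,1.128,False
aluminum,2.699,40,3.375e-07,0.5685,False
aluminum,2.699,50,2.16e-07,0.3681,False
aluminum,2.699,60,1.5e-07,0.2778,False
aluminum,2.699,80,8.4375e-08,0.2018,False
aluminum,2.699,100,5.4e-08,0.1704,False
aluminum,2.699,150,2.4e-08,0.1378,False
cdte,5.85,40,6.3225e-07,1.64,False
cdte,5.85,50,4.0464e-07,0.95,False
cdte,5.85,60,2.81e-07,0.61,False
cdte,5.85,80,1.580625e-07,0.30,False
cdte,5.85,100,1.0116e-07,0.20,False
cdte,5.85,150,4.496e-08,0.10,False
vacuum,1e-12,60,0.0,0.0,True
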