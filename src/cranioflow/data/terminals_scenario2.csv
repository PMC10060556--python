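name,attach_node,territory,reference,Rp_si,Rd_si,C_si,provenance
thoracic_aorta,aorta3,thoracic_aorta,venous_source,34361777.8,137447111,8.73063093e-09,calibrated: sized for 72.00%% of cardiac output at 92 mmHg mean pressure; tau=1.2 s
brachial_r,sub_r_d,brachial-R,venous_source,449826909,1.79930764e+09,6.66923196e-10,calibrated: sized for 5.50%% of cardiac output at 92 mmHg mean pressure; tau=1.2 s
brachial_l,sub_l_d,brachial-L,venous_source,449826909,1.79930764e+09,6.66923196e-10,calibrated: sized for 5.50%% of cardiac output at 92 mmHg mean pressure; tau=1.2 s
eca_r,cca_r_d,ECA-R,venous_source,618512000,2.474048e+09,4.85035052e-10,calibrated: sized for 4.00%% of cardiac output at 92 mmHg mean pressure; tau=1.2 s
eca_l,cca_l_d,ECA-L,venous_source,618512000,2.474048e+09,4.85035052e-10,calibrated: sized for 4.00%% of cardiac output at 92 mmHg mean pressure; tau=1.2 s
mca_r,ica_r_d,MCA-R,icp_coupled,1.17521633e+09,4.70086531e+09,3.40362868e-10,calibrated: sized for 1.96%% of cardiac output at 92 mmHg mean pressure; tau=1.6 s
mca_l,ica_l_d,MCA-L,icp_coupled,1.17521633e+09,4.70086531e+09,3.40362868e-10,calibrated: sized for 1.96%% of cardiac output at 92 mmHg mean pressure; tau=1.6 s
aca_r,aca_r_j,ACA-R,icp_coupled,1.62212958e+09,6.48851831e+09,1.6182431e-10,calibrated: sized for 1.42%% of cardiac output at 92 mmHg mean pressure; tau=1.05 s
aca_l,aca_l_j,ACA-L,icp_coupled,1.62212958e+09,6.48851831e+09,1.6182431e-10,calibrated: sized for 1.42%% of cardiac output at 92 mmHg mean pressure; tau=1.05 s
pca_r,pca_r_j,PCA-R,icp_coupled,2.15273271e+09,8.61093084e+09,1.1032489e-10,calibrated: sized for 1.07%% of cardiac output at 92 mmHg mean pressure; tau=0.95 s
pca_l,pca_l_j,PCA-L,icp_coupled,2.15273271e+09,8.61093084e+09,1.1032489e-10,calibrated: sized for 1.07%% of cardiac output at 92 mmHg mean pressure; tau=0.95 s
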