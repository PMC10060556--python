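name,prox,distal,length_cm,radius_cm,R_si,L_si,C_si,law,provenance
asc_aorta,heart,aorta1,4,1.2,19648.7584,92840.3835,3.13796075e-10,aorta,R/L anatomy-derived; C replaced by age-dependent aorta law
aortic_arch_1,aorta1,aorta2,2,1.12,12946.668,53288.4854,1.36675624e-10,aorta,R/L anatomy-derived; C replaced by age-dependent aorta law
aortic_arch_2,aorta2,aorta3,3.9,1.07,30306.0686,113850.903,2.43252429e-10,aorta,R/L anatomy-derived; C replaced by age-dependent aorta law
brachiocephalic,aorta1,brach_j,3.4,0.62,234375.529,295620.784,7.11997886e-11,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
cca_r,brach_j,cca_r_d,17.7,0.37,9619809.59,4321248.53,1.31280852e-10,cca,R/L anatomy-derived; C replaced by age-dependent cca law
cca_l,aorta2,cca_l_d,20.8,0.37,11304635,5078077.37,1.54273543e-10,cca,R/L anatomy-derived; C replaced by age-dependent cca law
subclavian_r,brach_j,sub_r_d,3.4,0.42,1112965.91,644198.579,3.26154185e-11,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
subclavian_l,aorta3,sub_l_d,3.4,0.42,1112965.91,644198.579,3.26154185e-11,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
vertebral_r,sub_r_d,bas_p,14.8,0.136,440662595,26743812.9,7.17075744e-12,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
vertebral_l,sub_l_d,bas_p,14.8,0.136,440662595,26743812.9,7.17075744e-12,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
ica_r_1,cca_r_d,ica_r_m,17.7,0.25,46154424.2,9465262.78,5.56600807e-11,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
ica_l_1,cca_l_d,ica_l_m,17.7,0.25,46154424.2,9465262.78,5.56600807e-11,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
ica_r_2,ica_r_m,ica_r_d,0.5,0.2,3183098.86,417781.726,8.67962485e-13,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
ica_l_2,ica_l_m,ica_l_d,0.5,0.2,3183098.86,417781.726,8.67962485e-13,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
basilar,bas_p,bas_d,2.9,0.162,42888222.3,3693238.85,2.58971636e-12,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
pcoa_r,ica_r_d,pca_r_j,1.5,0.073,538021863,9407732.61,7.96972279e-14,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
pcoa_l,ica_l_d,pca_l_j,1.5,0.073,538021863,9407732.61,7.96972279e-14,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
aca_a1_r,ica_r_d,aca_r_j,1.2,0.117,65228577.1,2929874.03,3.36865893e-13,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
aca_a1_l,ica_l_d,aca_l_j,1.2,0.117,65228577.1,2929874.03,3.36865893e-13,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
acoa,aca_l_j,aca_r_j,0.3,0.074,101904763,1831037.51,1.66827757e-14,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
pca_p1_r,bas_d,pca_r_j,0.5,0.107,38853934.1,1459626.96,1.01412619e-13,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
pca_p1_l,bas_d,pca_l_j,0.5,0.107,38853934.1,1459626.96,1.01412619e-13,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
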