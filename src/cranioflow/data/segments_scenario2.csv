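name,prox,distal,length_cm,radius_cm,R_si,L_si,C_si,law,provenance
asc_aorta,heart,aorta1,4.32,1.2,21220.6591,100267.614,3.38899761e-10,aorta,R/L anatomy-derived; C replaced by age-dependent aorta law
aortic_arch_1,aorta1,aorta2,2.16,1.12,13982.4014,57551.5642,1.47609674e-10,aorta,R/L anatomy-derived; C replaced by age-dependent aorta law
aortic_arch_2,aorta2,aorta3,4.212,1.07,32730.5541,122958.975,2.62712624e-10,aorta,R/L anatomy-derived; C replaced by age-dependent aorta law
brachiocephalic,aorta1,brach_j,3.672,0.5704,353333.415,377209.885,6.5081925e-11,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
cca_r,brach_j,cca_r_d,19.116,0.37,10389394.4,4666948.41,1.4178332e-10,cca,R/L anatomy-derived; C replaced by age-dependent cca law
cca_l,aorta2,cca_l_d,22.464,0.37,12209005.8,5484323.56,1.66615427e-10,cca,R/L anatomy-derived; C replaced by age-dependent cca law
subclavian_r,brach_j,sub_r_d,3.672,0.3864,1677854.54,821992.516,2.97537471e-11,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
subclavian_l,aorta3,sub_l_d,3.672,0.3864,1677854.54,821992.516,2.97537471e-11,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
vertebral_r,sub_r_d,bas_p,15.984,0.12512,664321998,34124903,5.72871578e-12,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
vertebral_l,sub_l_d,bas_p,15.984,0.12512,664321998,34124903,5.72871578e-12,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
ica_r_1,cca_r_d,ica_r_m,19.116,0.23,69580217.7,12077603.7,4.87579321e-11,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
ica_l_1,cca_l_d,ica_l_m,19.116,0.23,69580217.7,12077603.7,4.87579321e-11,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
ica_r_2,ica_r_m,ica_r_d,0.54,0.184,4798688.66,533086.323,7.2905759e-13,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
ica_l_2,ica_l_m,ica_l_d,0.54,0.184,4798688.66,533086.323,7.2905759e-13,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
basilar,bas_p,bas_d,3.132,0.14904,64656246.9,4712544.84,2.0999745e-12,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
pcoa_r,ica_r_d,pca_r_j,1.62,0.06716,811096207,12004195.7,6.5344867e-14,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
pcoa_l,ica_l_d,pca_l_j,1.62,0.06716,811096207,12004195.7,6.5344867e-14,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
aca_a1_r,ica_r_d,aca_r_j,1.296,0.10764,98335504.6,3738497.11,2.68610331e-13,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
aca_a1_l,ica_l_d,aca_l_j,1.296,0.10764,98335504.6,3738497.11,2.68610331e-13,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
acoa,aca_l_j,aca_r_j,0.324,0.06808,153626780,2336390.02,1.36637694e-14,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
pca_p1_r,bas_d,pca_r_j,0.54,0.09844,58574345.6,1862472.96,8.10662804e-14,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
pca_p1_l,bas_d,pca_l_j,0.54,0.09844,58574345.6,1862472.96,8.10662804e-14,,anatomy-derived: R=8*mu*l/(pi r^4); L=rho*l/(pi r^2); C=3*pi*r^3*l/(2Eh); exponential wall-stiffness law
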