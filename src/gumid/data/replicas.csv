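gum,pigment_element,pigment,ageing,dialect,xylose,arabinose,rhamnose,fucose,galacturonic_acid,glucuronic_acid,mannose,galactose,printed_correlation,literature_scheme_outcome
arabic,none,none,n,GCI,0.2,37.2,18.3,0.1,,,0.0,44.3,1.00,A
arabic,none,none,n,DCCI,0.0,25.7,13.3,0.0,0.0,11.7,0.0,49.3,1.00,A
arabic,none,none,W,GCI,0.2,37.8,18.7,0.1,,,0.0,43.1,1.00,A
arabic,none,none,O,GCI,0.6,39.9,19.4,0.0,,,0.0,40.2,0.99,A
arabic,none,none,SB2,DCCI,0.0,36.0,17.7,0.0,0.0,11.2,0.0,48.7,0.99,A
arabic,Hg,vermilion,n,GCI,0.4,38.8,18.5,0.1,,,0.0,42.2,1.00,A
arabic,Hg,vermilion,W,GCI,0.6,39.9,19.3,0.0,,,0.0,40.2,0.99,A
arabic,Hg,vermilion,O,GCI,0.6,38.8,17.9,0.2,,,0.0,42.6,1.00,A
arabic,Si,ultramarine,n,GCI,0.3,42.1,23.8,0.0,,,0.0,33.8,0.95,A
arabic,Si,ultramarine,W,GCI,0.6,43.7,21.6,0.0,,,0.0,34.2,0.95,A
arabic,Si,ultramarine,O,GCI,0.3,42.0,21.3,0.3,,,0.0,36.2,0.97,A
arabic,Si,ultramarine,n,DCCI,0.3,31.3,16.5,0.0,0.0,9.7,0.2,42.0,0.98,A
arabic,Si,ultramarine,SB1,DCCI,0.3,30.6,14.1,0.0,0.0,3.6,0.2,51.2,0.98,A
arabic,Si,ultramarine,SB2,DCCI,0.4,28.4,12.5,0.0,0.0,7.4,0.2,51.1,0.99,A
arabic,Cu,malachite,n,GCI,0.2,37.0,19.4,0.0,,,0.0,43.5,1.00,A
arabic,Cu,malachite,W,GCI,0.6,36.3,19.0,0.0,,,0.0,44.1,1.00,A
arabic,Cu,malachite,O,GCI,0.0,40.4,20.2,0.0,,,0.0,39.4,0.99,A
arabic,Cu,copper_acetate,n,DCCI,0.3,39.4,11.8,0.0,0.0,4.8,0.1,43.5,0.94,A
arabic,Cu,copper_acetate,SB1,DCCI,0.5,31.9,11.5,0.0,0.0,7.2,0.2,48.7,0.99,A
arabic,Cu,copper_acetate,SB2,DCCI,0.1,31.9,8.9,0.0,0.1,6.2,0.1,52.7,0.98,A
arabic,C,vine_black,n,GCI,0.1,36.3,16.4,0.1,,,0.1,46.9,1.00,A
arabic,C,vine_black,W,GCI,0.0,36.6,16.1,0.0,,,0.2,47.0,1.00,A
arabic,C,vine_black,O,GCI,0.0,36.1,16.6,0.1,,,0.1,47.2,1.00,A
arabic,Pb,lead_white,n,GCI,0.7,54.9,26.9,0.2,,,0.0,17.3,0.73,A
arabic,Pb,lead_white,W,GCI,0.3,46.2,22.8,0.2,,,0.0,30.5,0.92,A
arabic,Pb,lead_white,O,GCI,0.3,47.3,23.1,0.0,,,0.0,29.3,0.90,A
arabic,Pb,minium,n,DCCI,0.4,33.7,15.5,0.0,0.0,11.8,0.2,38.3,0.96,A
arabic,Pb,minium,SB1,DCCI,0.1,25.3,14.2,0.0,0.0,7.8,0.1,52.5,1.00,A
arabic,Pb,minium,SB2,DCCI,0.1,26.2,10.9,0.0,0.0,11.9,0.1,50.8,1.00,A
arabic,Fe,yellow_ochre,n,GCI,0.1,36.0,16.5,0.1,,,0.1,47.2,1.00,A
arabic,Fe,yellow_ochre,W,GCI,0.1,36.0,16.9,0.1,,,0.2,46.8,1.00,A
arabic,Fe,yellow_ochre,O,GCI,0.0,35.4,16.2,0.1,,,0.1,48.1,1.00,A
arabic,Fe,red_bole,n,DCCI,0.2,23.0,11.9,0.0,0.0,8.7,0.4,55.8,0.99,A
arabic,Fe,red_bole,SB1,DCCI,0.0,29.6,16.9,0.0,0.0,3.5,0.0,50.0,0.98,A
arabic,Fe,red_bole,SB2,DCCI,0.1,26.7,12.2,0.0,0.1,11.4,0.1,49.4,1.00,A
tragacanth,none,none,n,GCI,29.2,47.7,1.5,11.1,,,0.0,10.5,1.00,T
tragacanth,none,none,n,DCCI,23.5,40.2,2.3,8.0,14.1,0.6,0.0,11.3,1.00,T
tragacanth,none,none,W,GCI,29.3,47.1,1.6,11.1,,,0.0,10.9,1.00,T
tragacanth,none,none,O,GCI,29.7,46.9,1.6,10.9,,,0.0,11.0,1.00,T
tragacanth,none,none,SB2,DCCI,22.5,39.0,3.4,8.3,15.1,0.4,0.0,11.1,1.00,no
tragacanth,C,vine_black,n,GCI,28.5,47.4,1.7,11.0,,,0.0,11.3,1.00,T
tragacanth,C,vine_black,W,GCI,27.8,44.9,4.6,10.8,,,0.0,12.0,1.00,T
tragacanth,C,vine_black,O,GCI,28.6,45.5,3.6,10.7,,,0.0,11.7,1.00,T
tragacanth,Pb,lead_white,n,GCI,24.7,54.7,1.2,16.1,,,0.0,3.3,0.97,T
tragacanth,Pb,lead_white,W,GCI,25.4,53.2,1.1,14.7,,,0.0,5.6,0.98,T
tragacanth,Pb,lead_white,O,GCI,29.7,49.4,1.7,12.5,,,0.0,6.7,1.00,T
tragacanth,Pb,minium,n,DCCI,33.0,39.1,2.9,7.4,1.4,0.6,0.0,15.6,0.92,T
tragacanth,Pb,minium,SB1,DCCI,30.9,41.3,3.4,7.0,0.9,0.3,0.0,16.2,0.92,no
tragacanth,Pb,minium,SB2,DCCI,16.2,59.5,3.1,5.3,0.2,0.1,0.0,15.6,0.91,no
tragacanth,Hg,vermilion,n,GCI,27.6,49.6,1.6,10.5,,,0.0,10.6,1.00,T
tragacanth,Hg,vermilion,W,GCI,25.9,51.7,2.0,10.0,,,0.0,10.4,0.99,T
tragacanth,Hg,vermilion,O,GCI,28.5,47.7,2.7,8.8,,,0.0,12.3,1.00,T
tragacanth,Si,ultramarine,n,GCI,20.3,57.1,1.2,16.6,,,0.0,4.8,0.95,T
tragacanth,Si,ultramarine,W,GCI,18.7,59.1,0.8,14.6,,,0.0,6.9,0.95,no
tragacanth,Si,ultramarine,O,GCI,24.1,54.8,1.2,13.9,,,0.0,6.0,0.98,T
tragacanth,Si,ultramarine,n,DCCI,25.2,45.8,3.0,9.5,0.2,0.3,0.0,16.0,0.93,no
tragacanth,Si,ultramarine,SB1,DCCI,20.1,46.2,2.6,4.1,0.0,0.0,0.0,27.0,0.87,no
tragacanth,Si,ultramarine,SB2,DCCI,25.6,47.5,3.0,8.4,0.0,0.2,0.0,15.2,0.94,no
tragacanth,Fe,yellow_ochre,n,GCI,27.3,50.8,1.3,12.5,,,0.0,8.1,0.99,T
tragacanth,Fe,yellow_ochre,W,GCI,27.7,46.8,3.9,11.0,,,0.0,10.5,1.00,T
tragacanth,Fe,yellow_ochre,O,GCI,27.8,44.7,3.6,10.8,,,0.0,13.1,1.00,T
tragacanth,Fe,red_bole,n,DCCI,30.5,37.9,2.6,12.3,4.1,0.4,0.0,12.2,0.94,no
tragacanth,Fe,red_bole,SB1,DCCI,26.5,39.4,3.5,10.4,5.1,0.0,0.0,14.9,0.96,no
tragacanth,Fe,red_bole,SB2,DCCI,29.1,43.4,2.9,11.3,0.1,0.2,0.3,12.6,0.93,no
tragacanth,Cu,malachite,n,GCI,7.2,72.0,0.9,18.6,,,0.0,1.3,0.85,no
tragacanth,Cu,malachite,W,GCI,3.3,71.2,1.4,23.7,,,0.0,0.5,0.80,T
tragacanth,Cu,malachite,O,GCI,10.1,67.9,1.8,20.2,,,0.0,0.0,0.86,T
tragacanth,Cu,copper_acetate,n,DCCI,13.2,37.8,5.6,3.2,4.6,9.2,0.0,26.5,0.78,T
tragacanth,Cu,copper_acetate,SB1,DCCI,9.7,41.5,6.8,3.5,3.1,4.7,0.0,30.8,0.75,T
tragacanth,Cu,copper_acetate,SB2,DCCI,10.9,47.6,4.1,2.1,0.4,3.1,0.0,31.8,0.77,no
fruit_tree,none,none,n,GCI,11.8,54.3,1.3,0.1,,,2.2,30.2,1.00,F
fruit_tree,none,none,n,DCCI,7.0,48.7,2.1,0.0,0.0,5.9,1.8,34.4,1.00,F
fruit_tree,none,none,W,GCI,12.4,54.9,1.4,0.1,,,1.2,30.1,1.00,F
fruit_tree,none,none,O,GCI,10.5,48.4,1.2,0.1,,,3.1,36.6,0.99,F
fruit_tree,none,none,SB2,DCCI,6.1,43.2,2.1,0.0,0.0,9.0,2.7,36.9,0.99,F
fruit_tree,Pb,lead_white,n,GCI,17.0,71.9,2.1,0.0,,,1.5,7.5,0.87,F
fruit_tree,Pb,lead_white,W,GCI,18.7,67.0,2.2,0.0,,,3.3,8.8,0.87,F
fruit_tree,Pb,lead_white,O,GCI,14.7,55.9,0.0,0.0,,,2.9,26.5,0.99,no
fruit_tree,Pb,minium,n,DCCI,6.8,53.0,1.1,0.1,0.0,3.7,3.8,31.5,0.99,F
fruit_tree,Pb,minium,SB1,DCCI,5.1,50.7,0.9,0.1,0.0,11.4,5.2,26.6,0.98,no
fruit_tree,Pb,minium,SB2,DCCI,3.6,53.9,1.0,0.0,0.0,3.6,3.5,34.3,0.99,F
fruit_tree,Si,ultramarine,n,GCI,8.6,54.2,2.5,0.0,,,1.4,33.3,1.00,F
fruit_tree,Si,ultramarine,W,GCI,14.9,79.3,1.8,0.5,,,1.8,1.8,0.83,F
fruit_tree,Si,ultramarine,O,GCI,10.1,53.6,1.4,0.0,,,2.9,31.9,1.00,F
fruit_tree,Si,ultramarine,n,DCCI,6.0,57.7,1.2,0.0,0.0,6.6,2.8,25.7,0.97,F
fruit_tree,Si,ultramarine,SB1,DCCI,7.8,55.6,1.2,0.0,0.0,7.2,2.6,25.6,0.98,F
fruit_tree,Si,ultramarine,SB2,DCCI,5.5,57.9,1.0,0.0,0.0,3.6,3.1,28.9,0.98,F
fruit_tree,C,vine_black,n,GCI,12.0,51.0,1.7,0.0,,,1.3,34.0,1.00,F
fruit_tree,C,vine_black,W,GCI,16.4,54.1,1.6,0.0,,,1.6,26.2,0.99,F
fruit_tree,C,vine_black,O,GCI,9.8,48.4,1.3,0.0,,,3.9,36.6,0.99,F
fruit_tree,Hg,vermilion,n,GCI,10.4,45.8,1.0,0.0,,,2.3,40.4,0.97,F
fruit_tree,Hg,vermilion,W,GCI,10.4,40.4,1.1,0.0,,,3.2,45.0,0.92,F
fruit_tree,Hg,vermilion,O,GCI,10.2,32.2,0.0,0.0,,,3.4,54.2,0.80,no
fruit_tree,Fe,yellow_ochre,n,GCI,10.6,49.8,2.2,0.0,,,3.1,34.4,1.00,F
fruit_tree,Fe,yellow_ochre,W,GCI,12.2,53.1,2.0,0.0,,,2.0,30.6,1.00,F
fruit_tree,Fe,yellow_ochre,O,GCI,12.0,45.8,1.2,0.0,,,3.6,37.3,0.98,F
fruit_tree,Fe,red_bole,n,DCCI,3.7,51.1,0.9,0.0,0.1,12.9,3.2,28.2,0.98,no
fruit_tree,Fe,red_bole,SB1,DCCI,6.8,58.7,1.4,0.0,0.0,5.2,2.1,25.9,0.97,F
fruit_tree,Fe,red_bole,SB2,DCCI,5.0,57.7,1.0,0.0,0.0,4.1,3.0,29.3,0.98,F
fruit_tree,Cu,malachite,n,GCI,8.3,83.0,1.8,0.3,,,0.0,6.7,0.87,no
fruit_tree,Cu,malachite,W,GCI,12.5,79.2,4.2,0.0,,,0.0,4.2,0.85,no
fruit_tree,Cu,malachite,O,GCI,9.1,90.9,0.0,0.0,,,0.0,0.0,0.83,no
fruit_tree,Cu,copper_acetate,n,DCCI,3.8,60.8,0.7,0.1,0.0,7.4,3.4,23.8,0.96,no
fruit_tree,Cu,copper_acetate,SB1,DCCI,6.6,52.8,0.6,0.0,0.0,12.1,3.5,24.4,0.97,no
fruit_tree,Cu,copper_acetate,SB2,DCCI,2.7,61.3,0.5,0.0,0.0,1.7,2.6,31.2,0.98,no
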