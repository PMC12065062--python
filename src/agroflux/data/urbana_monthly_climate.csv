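year,month,tmean_c,precip_mm
2020,1,-0.2,82.8
2020,2,-0.9,18.5
2020,3,6.3,70.9
2020,4,9.5,70.1
2020,5,15.5,106.4
2020,6,23.2,129.8
2020,7,24.9,95.5
2020,8,22.3,39.6
2020,9,18.0,68.3
2020,10,11.2,49.0
2020,11,7.0,59.4
2020,12,0.6,33.3
2021,1,-1.1,45.0
2021,2,-5.6,35.1
2021,3,7.5,109.0
2021,4,11.6,48.8
2021,5,15.5,89.7
2021,6,23.5,166.6
2021,7,22.9,105.9
2021,8,23.5,50.5
2021,9,20.8,78.2
2021,10,15.5,136.9
2021,11,4.4,30.5
2021,12,4.7,55.9
2022,1,-5.0,11.2
2022,2,-2.1,30.2
2022,3,5.7,113.5
2022,4,10.4,69.1
2022,5,19.2,95.5
2022,6,24.0,32.0
2022,7,24.1,63.0
2022,8,22.3,88.4
2022,9,18.8,57.4
2022,10,12.0,57.9
2022,11,5.6,45.7
2022,12,-0.2,65.5
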