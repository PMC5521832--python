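drug,age_band,case,total,event_total,n_total,prr,prr_lo,prr_hi,chi2,ror,ror_lo,ror_hi
All CEPs,all,744,1163,14593,338224,15.6,13.8,17.6,10046.1,41.4,36.7,46.8
All CEPs,10-19,14,30,14593,338224,10.8,5.3,22.2,120.3,19.4,9.5,39.8
All CEPs,20-29,113,198,14593,338224,13.3,10.1,17.7,1322.9,29.7,22.4,39.4
All CEPs,30-39,243,355,14593,338224,16.1,12.9,20.2,3525.3,48.9,39.1,61.2
All CEPs,40-49,298,400,14593,338224,17.6,14.1,22.1,4761.4,66.1,52.8,82.8
All CEPs,50-59,35,52,14593,338224,15.6,8.8,27.9,484.7,45.8,25.6,81.7
Drospirenone-EE,all,237,332,14593,338224,16.8,13.2,21.3,3604.9,56.2,44.3,71.4
Drospirenone-EE,10-19,7,12,14593,338224,13.5,4.3,42.6,72.2,31.1,9.9,97.9
Drospirenone-EE,20-29,37,52,14593,338224,16.5,9.1,30.1,546.7,54.8,30.1,99.9
Drospirenone-EE,30-39,79,98,14593,338224,18.8,11.4,31.0,1363.8,92.7,56.2,153.0
Drospirenone-EE,40-49,86,101,14593,338224,19.8,11.5,34.4,1579.5,127.9,73.9,221.4
Drospirenone-EE,50-59,12,14,14593,338224,19.9,4.4,88.8,205.4,133.2,29.8,595.1
Norethisterone-EE,all,198,351,14593,338224,13.2,10.7,16.4,2297.2,29.1,23.5,35.9
Norethisterone-EE,10-19,2,2,14593,338224,,,,,,,
Norethisterone-EE,20-29,20,54,14593,338224,8.6,4.9,14.9,132.2,13.1,7.5,22.7
Norethisterone-EE,30-39,54,99,14593,338224,12.7,8.5,18.8,593.1,26.7,18.0,39.7
Norethisterone-EE,40-49,108,155,14593,338224,16.3,11.5,22.9,1588.9,51.3,36.4,72.3
Norethisterone-EE,50-59,6,12,14593,338224,11.6,3.7,35.9,50.1,22.2,7.2,68.8
Levonorgestrel-EE,all,140,213,14593,338224,15.4,11.6,20.4,1932.2,42.9,32.3,57.0
Levonorgestrel-EE,10-19,1,4,14593,338224,,,,,,,
Levonorgestrel-EE,20-29,19,32,14593,338224,13.8,6.8,27.9,221.9,32.5,16.0,65.7
Levonorgestrel-EE,30-39,54,77,14593,338224,16.3,10.0,26.6,792.2,52.3,32.1,85.2
Levonorgestrel-EE,40-49,56,76,14593,338224,17.1,10.3,28.6,869.3,62.3,37.4,103.9
Levonorgestrel-EE,50-59,7,11,14593,338224,14.8,4.3,50.4,79.9,38.8,11.4,132.7
Desogestrel-EE,all,118,177,14593,338224,15.6,11.4,21.3,1652.6,44.7,32.7,61.1
Desogestrel-EE,10-19,3,7,14593,338224,9.9,2.2,44.4,16.7,16.6,3.7,74.3
Desogestrel-EE,20-29,25,43,14593,338224,13.5,7.4,24.7,288.9,30.9,16.8,56.6
Desogestrel-EE,30-39,43,54,14593,338224,18.5,9.5,35.9,723.9,87.0,44.8,168.6
Desogestrel-EE,40-49,34,43,14593,338224,18.4,8.8,38.3,564.2,84.0,40.3,175.1
Desogestrel-EE,50-59,2,3,14593,338224,,,,,44.4,4.0,489.3
Norgestrel-EE,all,71,112,14593,338224,14.8,10.0,21.7,932.9,38.6,26.3,56.7
Norgestrel-EE,10-19,1,5,14593,338224,,,,,,,
Norgestrel-EE,20-29,12,19,14593,338224,14.6,5.8,37.2,145.4,38.1,15.0,96.7
Norgestrel-EE,30-39,25,39,14593,338224,14.9,7.7,28.6,323.4,39.7,20.6,76.3
Norgestrel-EE,40-49,22,33,14593,338224,15.5,7.5,31.9,295.9,44.4,21.5,91.6
Norgestrel-EE,50-59,8,12,14593,338224,15.5,4.7,51.3,98.4,44.4,13.4,147.4
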