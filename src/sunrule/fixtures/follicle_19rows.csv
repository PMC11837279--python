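MQ8,MQ3,NH3,T2602,NO2,T822,HCHO,T2620,MS1100,MQ7,MQ6,MQ4,MQ135,TEMP1,NEM1,Class
216,539.2,594.8,932.4,98.8,843,232.4,963.2,220.5,137,283.8,110.8,930,34.8,27.4,A
198.7,519.1,647.3,927.8,77.7,837.3,162,962.8,209,129,269.9,104.6,930,36,24.9,A
198.5,511.1,600,928.4,77.4,862,137.4,963,206.4,130.3,270,109.4,931.4,38,26,U
192.09,498.18,610.91,923.45,70.55,853.55,121.55,960,199.36,126.91,264.45,106,931.55,39,24.45,U
187.82,486.73,622.09,923.36,69.18,842.36,112.45,956,193.45,125.45,260.73,104.09,931.09,40,23,A
187.27,482.09,631.64,920.09,69.55,836.91,108.73,951.36,190,124.18,259.45,102,930.09,41,22.09,U
262.5,525.7,769.2,941.2,230.5,781.2,127.7,896.1,421.3,251,321.8,251,927,30,25.8,U
266.9,525.4,777,940,227.7,697,134.9,889,410.5,251,327.1,240.8,927.8,30.8,27.4,U
273.7,527.4,778.3,935.9,225.4,761.1,119.6,882.5,402.6,250.6,334.7,227.8,924.5,31,29,A
287,532.36,769.82,934.09,214.55,762.64,125.18,869.36,388.55,251.64,348.27,218.27,925.82,31.27,29,A
252.82,573.18,537.18,933.36,53,887,133.36,955.09,278.45,159.91,328.64,129.73,900,33,31,A
180.8,490.6,651.8,911.4,62.1,830,87.7,945.1,175,123.8,252.6,96.2,886.8,36,27.7,U
177.3,479.8,653.7,910.3,63,827.4,86,944.6,170,119.7,249.3,93.4,873.5,36.2,27,A
171.7,466.5,666,907.9,63.1,813.7,83.1,942,161.6,116.9,244.8,90.7,869.3,37,25.8,A
177.2,471.2,645,926.9,66.2,814,107.5,942.8,169.7,121.1,250.4,95,893.6,38,26.6,A
173.9,461.4,656.4,916.7,64,817,92.8,941.9,166.3,118.8,247.1,90.7,895.4,39,25,U
172.2,457.3,661.1,913.4,64,812.8,89.2,940.1,162.9,118,245.6,89.3,896,40,24.4,A
265.5,582.5,544.3,952.7,52.9,868.2,249.6,949.9,297.8,160,340.8,127.4,893.1,34,31.4,A
216,542.5,597.7,932.3,56.5,850.6,123.2,952.6,216.1,140,287.2,110,878,34,31.5,A
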