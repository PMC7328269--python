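#!/usr/bin/env Rscript
# Independent reference for the parametric EB batch correction: reads a
# probes x samples CSV, batch labels and optional covariate column, runs
# sva::ComBat, writes the corrected matrix as CSV.
suppressMessages(library(sva))
args <- commandArgs(trailingOnly = TRUE)
dat <- as.matrix(read.csv(args[[1]], header = FALSE))
batch <- scan(args[[2]], what = integer(), quiet = TRUE)
mod <- NULL
if (length(args) >= 4 && nzchar(args[[4]])) {
  grp <- scan(args[[4]], what = integer(), quiet = TRUE)
  mod <- model.matrix(~grp)
}
res <- ComBat(dat = dat, batch = batch, mod = mod, par.prior = TRUE)
write.table(res, args[[3]], sep = ",", row.names = FALSE, col.names = FALSE)
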